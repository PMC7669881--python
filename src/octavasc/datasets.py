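"""Published reference measurements used in validation examples.

Two small tables accompany the package: per-subject telencephalic
vessel diameters from in vivo OCT angiography of adult medaka (the
smallest and largest clearly delineated vessel per fish), and the
major/minor axes of red blood cells measured on histological sections
of the same animals.  They serve as fixed inputs for checking the
diameter arithmetic (``d -> D_FWHM``) and the mean +/- population-SD
summaries the pipeline reports.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["vessel_diameters", "rbc_axes"]


def vessel_diameters() -> pd.DataFrame:
    """Per-subject vessel diameters (µm): d, D_FWHM and D_edge, small and large.

    ``d`` is the full width at half maximum of the vessel intensity
    profile (an inner-diameter estimate), ``d_fwhm = d * sqrt(4/3)``
    the estimated outer diameter, and ``d_edge`` the distance between
    the profile maxima (the largest plausible outer diameter).
    """
    rows = [
        ("subject1", 6.6, 24.7, 7.6, 28.5, 12.4, 35.1),
        ("subject2", 9.4, 19.7, 10.9, 22.8, 15.6, 30.9),
        ("subject3", 6.3, 25.2, 7.3, 29.1, 13.6, 39.1),
        ("subject6", 5.7, 22.5, 6.6, 26.0, 12.1, 39.0),
        ("subject7", 9.0, 19.7, 10.4, 22.7, 21.0, 28.2),
        ("subject8", 5.6, 30.5, 6.5, 35.3, 9.0, 43.4),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject",
            "d_small",
            "d_large",
            "d_fwhm_small",
            "d_fwhm_large",
            "d_edge_small",
            "d_edge_large",
        ],
    )


def rbc_axes() -> pd.DataFrame:
    """Major/minor axes (µm) of red blood cells in histological sections.

    Each row is one cell; ``slice`` identifies the histological section
    (L/R = vessel on the left/right side of the brain).
    """
    rows = [
        ("slice1", 7.3, 2.8),
        ("slice1", 7.0, 3.0),
        ("slice1", 7.4, 2.1),
        ("slice1", 7.5, 3.3),
        ("slice2L", 5.9, 2.3),
        ("slice2L", 8.7, 3.6),
        ("slice2L", 7.7, 3.7),
        ("slice2L", 8.1, 3.5),
        ("slice2L", 8.3, 3.0),
        ("slice2L", 7.1, 2.9),
        ("slice2L", 8.3, 3.0),
        ("slice2L", 8.4, 3.2),
        ("slice2L", 9.0, 3.9),
        ("slice2R", 7.6, 1.9),
        ("slice2R", 6.6, 2.2),
        ("slice3L", 7.8, 3.3),
        ("slice3R", 5.4, 2.8),
        ("slice4", 7.0, 2.2),
        ("slice4", 7.0, 3.9),
        ("slice4", 6.5, 3.8),
        ("slice4", 6.9, 2.6),
        ("slice4", 6.1, 3.7),
    ]
    return pd.DataFrame(rows, columns=["slice", "major_um", "minor_um"])
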