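"""In-memory containers for 3D OCT intensity volumes.

Axis convention throughout the package: axis 0 = x (fast lateral scan),
axis 1 = y (slow lateral scan), axis 2 = z (depth / axial).  A sagittal
section is a y-z plane at fixed x, an axial section an x-z plane at
fixed y, and a coronal section an x-y plane at fixed z.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["AcquisitionGeometry", "Volume", "AXIS_NAMES", "axis_index"]

AXIS_NAMES = ("x", "y", "z")


def axis_index(axis: int | str) -> int:
    """Normalize an axis given as 0/1/2 or 'x'/'y'/'z'."""
    if isinstance(axis, str):
        try:
            return AXIS_NAMES.index(axis.lower())
        except ValueError:
            raise ValueError(f"unknown axis {axis!r}; expected one of {AXIS_NAMES}") from None
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    return int(axis)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Scan geometry: per-axis fields of view (mm) and sample counts.

    The voxel spacing per axis in µm is ``fov_mm * 1000 / dims``.
    """

    fov_mm: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if len(self.fov_mm) != 3 or len(self.dims) != 3:
            raise ValueError("fov_mm and dims must be 3-tuples (x, y, z)")
        if min(self.fov_mm) <= 0:
            raise ValueError("fields of view must be positive")
        if min(self.dims) < 1:
            raise ValueError("dims must be >= 1 per axis")

    @property
    def spacing_um(self) -> tuple[float, float, float]:
        return tuple(f * 1000.0 / n for f, n in zip(self.fov_mm, self.dims))  # type: ignore[return-value]


@dataclass
class Volume:
    """A 3D scalar intensity grid with physical per-axis spacing.

    Parameters
    ----------
    intensities:
        3D array indexed ``[x, y, z]``.
    spacing_um:
        Voxel pitch per axis in micrometres, strictly positive.
    value_range:
        Nominal (min, max) of the intensity scale, e.g. ``(0, 65535)``
        for 16-bit data; informational only.
    """

    intensities: np.ndarray
    spacing_um: tuple[float, float, float]
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if len(self.spacing_um) != 3 or min(self.spacing_um) <= 0:
            raise ValueError("spacing_um must be three strictly positive values")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def astype_float(self) -> "Volume":
        """Return a copy with double-precision floating-point intensities."""
        return self.with_data(self.intensities.astype(np.float64))

    def with_data(
        self,
        data: np.ndarray,
        spacing_um: tuple[float, float, float] | None = None,
        value_range: tuple[float, float] | None | str = "keep",
    ) -> "Volume":
        """New volume with replaced intensities (and optionally spacing)."""
        vr = self.value_range if value_range == "keep" else value_range
        return Volume(
            intensities=data,
            spacing_um=self.spacing_um if spacing_um is None else spacing_um,
            value_range=vr,  # type: ignore[arg-type]
        )
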