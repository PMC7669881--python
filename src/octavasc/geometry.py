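"""Spectral-domain OCT resolution and voxel-geometry arithmetic.

In SD-OCT the depth (axial) profile is the Fourier transform of the
recorded spectrum, so the sensor count and imaging depth fix a
pixel-limited axial resolution, and any spectral apodization window
broadens the axial point-spread function (PSF).  This module collects
that arithmetic: the pixel limit ``max_depth / (n_sensors / 2)``, the
FWHM broadening caused by a tapered-cosine (Tukey) window, the
refractive-index correction for resolution inside a medium, and the
isotropic voxel spacing used when resampling anisotropic volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import tukey

from .volume import AcquisitionGeometry

__all__ = [
    "SpectrometerSpec",
    "ResolutionQuery",
    "axial_pixel_limit",
    "windowed_axial_resolution",
    "resolution_in_medium",
    "isotropic_spacing",
    "round_half_away",
]


def round_half_away(x: float) -> int:
    """Round to the nearest integer with halves going away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class SpectrometerSpec:
    """Spectrometer parameters that determine axial sampling.

    Parameters
    ----------
    lambda_min_nm, lambda_max_nm:
        Edges of the detected spectral band in nanometres.
    n_sensors:
        Number of line-camera sensor elements (even).
    window_alpha:
        Taper fraction of the tapered-cosine (Tukey) apodization window,
        in [0, 1]; 0 is rectangular, 1 is a Hann window.
    max_depth_mm:
        Maximum imaging depth in air, in millimetres.
    """

    lambda_min_nm: float = 800.0
    lambda_max_nm: float = 1018.0
    n_sensors: int = 2048
    window_alpha: float = 0.4
    max_depth_mm: float = 1.91

    def __post_init__(self) -> None:
        if not self.lambda_min_nm < self.lambda_max_nm:
            raise ValueError("lambda_min_nm must be < lambda_max_nm")
        if self.n_sensors < 2 or self.n_sensors % 2 != 0:
            raise ValueError("n_sensors must be an even integer >= 2")
        if not 0.0 <= self.window_alpha <= 1.0:
            raise ValueError("window_alpha must lie in [0, 1]")
        if self.max_depth_mm <= 0:
            raise ValueError("max_depth_mm must be positive")


@dataclass(frozen=True)
class ResolutionQuery:
    """Refractive index of the medium a resolution figure refers to."""

    n: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")


def axial_pixel_limit(spec: SpectrometerSpec) -> float:
    """Pixel-limited axial resolution in micrometres.

    The spectrum of ``n_sensors`` samples yields ``n_sensors / 2``
    usable depth pixels over ``max_depth_mm``, so the depth-pixel pitch
    is ``max_depth / (n_sensors / 2)``.
    """
    return spec.max_depth_mm * 1000.0 / (spec.n_sensors / 2)


def _amplitude_psf_fwhm_pixels(n: int, alpha: float, pad_factor: int = 16) -> float:
    """FWHM, in depth pixels, of the amplitude PSF of a Tukey window.

    The window is zero-padded by ``pad_factor`` so that the discrete
    Fourier transform is sampled at sub-pixel resolution; the half-max
    crossings of the central peak of ``|FFT|`` are then localized by
    linear interpolation between bins.
    """
    w = tukey(n, alpha=alpha, sym=False)
    amp = np.abs(np.fft.fft(w, n=n * pad_factor))
    amp = np.fft.fftshift(amp)
    peak = int(np.argmax(amp))
    half = amp[peak] / 2.0

    def crossing(direction: int) -> float:
        i = peak
        while 0 < i < amp.size - 1 and amp[i + direction] >= half:
            i += direction
        j = i + direction
        # linear interpolation between the bracketing samples
        frac = (amp[i] - half) / (amp[i] - amp[j])
        return i + direction * frac

    width_bins = crossing(+1) - crossing(-1)
    return width_bins / pad_factor


def windowed_axial_resolution(spec: SpectrometerSpec, pad_factor: int = 16) -> float:
    """Axial resolution in air, in µm, after spectral apodization.

    Defined as the full width at half maximum of the amplitude PSF of
    the tapered-cosine window, in depth-pixel units, multiplied by the
    pixel-limited resolution.  A rectangular window (alpha = 0) gives
    the |sinc| amplitude PSF with FWHM ~= 1.21 pixels; broader tapers
    broaden the PSF monotonically.
    """
    fwhm_px = _amplitude_psf_fwhm_pixels(spec.n_sensors, spec.window_alpha, pad_factor)
    return fwhm_px * axial_pixel_limit(spec)


def resolution_in_medium(resolution_air_um: float, query: ResolutionQuery) -> float:
    """Scale a resolution figure from air into a medium of index n."""
    if resolution_air_um <= 0:
        raise ValueError("resolution_air_um must be positive")
    return resolution_air_um / query.n


def isotropic_spacing(geometry: AcquisitionGeometry) -> tuple[float, tuple[int, int, int]]:
    """Isotropic target spacing (µm) and target dims for a scan geometry.

    The x voxel pitch ``fov_x / nx`` is taken as the common spacing and
    the other axes are resampled to ``round(fov_axis / spacing)``
    samples (halves away from zero).
    """
    fx, fy, fz = geometry.fov_mm
    nx, ny, nz = geometry.dims
    if min(fx, fy, fz) <= 0:
        raise ValueError("fields of view must be positive")
    if min(nx, ny, nz) < 1:
        raise ValueError("dims must be >= 1")
    spacing = fx * 1000.0 / nx
    dims = tuple(round_half_away(f * 1000.0 / spacing) for f in (fx, fy, fz))
    return spacing, dims  # type: ignore[return-value]
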