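"""Volume conditioning chain for OCT angiography stacks.

The measurement-path pipeline, in order, is: conversion to double
precision, per-cross-section 5x5 adaptive Wiener filtering, per-column
z-axis outlier capping at 3 SD, proportional rescale to the 16-bit
range, and (for segmentation use) 3D non-local-means denoising.
Isotropic resampling corrects the anisotropic voxel aspect ratio, and a
perpendicular Gaussian "slab" filter improves the visibility of vessels
in a displayed section; the slab filter is a display aid only and is
never part of the measurement path.

All window/convolution operations use reflective boundary handling.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.restoration import denoise_nl_means

from .geometry import isotropic_spacing, round_half_away
from .volume import AcquisitionGeometry, Volume, axis_index

__all__ = [
    "wiener_slice_filter",
    "cap_outliers_z",
    "rescale_16bit",
    "estimate_noise_sd",
    "nlm_denoise",
    "resample_isotropic",
    "gaussian_slab_filter",
    "min_intensity_projection",
    "preprocess_pipeline",
]

logger = logging.getLogger(__name__)

UINT16_MAX = 65535.0


def _wiener2(image: np.ndarray, kernel: tuple[int, int]) -> np.ndarray:
    """Adaptive (locally linear MMSE) Wiener filter of one 2D image.

    Per-pixel local mean m and variance v are estimated over the
    rectangular window; the noise power is the mean of the local
    variances; the output is ``m + max(0, v - noise)/max(v, noise) *
    (x - m)``, which leaves flat regions at their local mean and
    preserves structure where the local variance exceeds the noise.
    """
    img = np.asarray(image, dtype=np.float64)
    local_mean = ndimage.uniform_filter(img, size=kernel, mode="reflect")
    local_sq = ndimage.uniform_filter(img * img, size=kernel, mode="reflect")
    local_var = np.maximum(local_sq - local_mean**2, 0.0)
    noise = float(local_var.mean())
    denom = np.maximum(local_var, noise)
    with np.errstate(invalid="ignore", divide="ignore"):
        gain = np.where(denom > 0, np.maximum(local_var - noise, 0.0) / denom, 0.0)
    return local_mean + gain * (img - local_mean)


def wiener_slice_filter(
    volume: Volume, kernel: tuple[int, int] = (5, 5), slice_axis: int | str = "y"
) -> Volume:
    """Apply an adaptive Wiener filter to every cross-section.

    ``slice_axis`` selects which axis is held fixed per section; the
    default ``"y"`` filters each x-z B-scan, the native acquisition
    frame.
    """
    ax = axis_index(slice_axis)
    data = volume.intensities.astype(np.float64)
    plane_shape = tuple(s for i, s in enumerate(data.shape) if i != ax)
    if kernel[0] > plane_shape[0] or kernel[1] > plane_shape[1]:
        raise ValueError(f"kernel {kernel} larger than cross-section {plane_shape}")
    out = np.empty_like(data)
    moved = np.moveaxis(data, ax, 0)
    out_moved = np.moveaxis(out, ax, 0)
    for i in range(moved.shape[0]):
        out_moved[i] = _wiener2(moved[i], kernel)
    return volume.with_data(out)


def cap_outliers_z(volume: Volume, k: float = 3.0) -> Volume:
    """Cap depth-axis outliers at ``mean +/- k * SD`` per (x, y) column.

    Statistics are the per-column mean and population SD along z; only
    values strictly beyond the thresholds are replaced (a value exactly
    at ``mean + k*SD`` passes through).  Constant columns have zero SD
    and are returned unchanged.
    """
    if volume.dims[2] < 2:
        raise ValueError("cap_outliers_z requires at least 2 samples along z")
    data = volume.intensities.astype(np.float64)
    m = data.mean(axis=2, keepdims=True)
    s = data.std(axis=2, keepdims=True)  # population SD (divisor n)
    hi = m + k * s
    lo = m - k * s
    out = np.where(data > hi, hi, data)
    out = np.where(out < lo, lo, out)
    return volume.with_data(out)


def rescale_16bit(volume: Volume) -> Volume:
    """Proportionally rescale intensities so min -> 0 and max -> 65535."""
    data = volume.intensities.astype(np.float64)
    vmin, vmax = float(data.min()), float(data.max())
    if vmax == vmin:
        logger.warning("rescale_16bit: constant volume, output set to all zeros")
        return volume.with_data(np.zeros_like(data), value_range=(0.0, UINT16_MAX))
    out = (data - vmin) / (vmax - vmin) * UINT16_MAX
    return volume.with_data(out, value_range=(0.0, UINT16_MAX))


def estimate_noise_sd(data: np.ndarray) -> float:
    """Robust noise SD estimate: scaled MAD of the Laplacian response.

    The Laplacian of i.i.d. noise with SD sigma has SD ``sigma *
    sqrt(sum of squared stencil weights)``; the median absolute
    deviation (scaled by 1.4826) makes the estimate insensitive to
    structure edges.
    """
    lap = ndimage.laplace(np.asarray(data, dtype=np.float64), mode="reflect")
    mad = np.median(np.abs(lap - np.median(lap)))
    stencil_norm = np.sqrt(4.0 * data.ndim**2 + 2.0 * data.ndim)  # center (2d)^2 + 2d ones
    return float(1.4826 * mad / stencil_norm)


def nlm_denoise(
    volume: Volume,
    patch: int = 3,
    search: int = 7,
    h: float | None = None,
) -> Volume:
    """3D non-local-means denoising.

    Each voxel is replaced by a weighted average of the voxels in its
    ``search``-cube, with weights ``exp(-max(0, d^2 - 2 sigma^2)/h^2)``
    on patch similarity ``d``.  ``h`` defaults to ``0.8 * sigma`` with
    sigma estimated by :func:`estimate_noise_sd`; the filter is fully
    deterministic.
    """
    if patch % 2 == 0 or search % 2 == 0 or patch < 1 or search < 1:
        raise ValueError("patch and search sizes must be odd and >= 1")
    if search < patch:
        raise ValueError("search window must be at least as large as the patch")
    data = volume.intensities.astype(np.float64)
    sigma = estimate_noise_sd(data)
    if h is None:
        h = 0.8 * sigma if sigma > 0 else 1.0
    out = denoise_nl_means(
        data,
        patch_size=patch,
        patch_distance=(search - 1) // 2,
        h=h,
        sigma=sigma,
        fast_mode=True,
        preserve_range=True,
    )
    return volume.with_data(out)


def resample_isotropic(
    volume: Volume, geometry: AcquisitionGeometry, order: int = 3
) -> Volume:
    """Resample to isotropic voxels at the x-axis pitch.

    The target spacing is ``fov_x / nx`` and each axis is resampled to
    ``round(fov_axis / spacing)`` samples (halves away from zero) by
    spline interpolation of the requested ``order`` (default cubic).
    Preserves the physical field of view within one voxel per axis.
    """
    if geometry.dims != volume.dims:
        raise ValueError(
            f"geometry dims {geometry.dims} inconsistent with volume dims {volume.dims}"
        )
    spacing, target_dims = isotropic_spacing(geometry)
    data = volume.intensities.astype(np.float64)
    if tuple(target_dims) == volume.dims:
        return volume.with_data(data, spacing_um=(spacing,) * 3)
    zoom = [t / s for t, s in zip(target_dims, volume.dims)]
    out = ndimage.zoom(data, zoom, order=order, mode="reflect", grid_mode=True)
    assert out.shape == tuple(target_dims)
    return volume.with_data(out, spacing_um=(spacing,) * 3)


def gaussian_slab_filter(
    volume: Volume, view_axis: int | str, sigma: float = 15.0
) -> Volume:
    """Smooth along the axis perpendicular to a display plane.

    For a requested viewing plane (named by the axis perpendicular to
    it), a 1D Gaussian of the given sigma (in voxels) is applied along
    that axis only; in-plane detail is untouched.  Display aid only.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    ax = axis_index(view_axis)
    data = volume.intensities.astype(np.float64)
    out = ndimage.gaussian_filter1d(data, sigma=sigma, axis=ax, mode="reflect")
    return volume.with_data(out)


def min_intensity_projection(
    volume: Volume, axis: int | str, slab: tuple[int, int]
) -> np.ndarray:
    """Per-pixel minimum over ``slab = (start, stop)`` along an axis.

    Dark tubular vessels survive the minimum, so a MinIP through a
    slab of sections renders the vasculature on a bright background.
    """
    ax = axis_index(axis)
    start, stop = slab
    n = volume.dims[ax]
    if not (0 <= start < stop <= n):
        raise ValueError(f"slab {slab} out of bounds for axis of length {n}")
    sl = [slice(None)] * 3
    sl[ax] = slice(start, stop)
    return np.min(volume.intensities[tuple(sl)], axis=ax)


def preprocess_pipeline(
    volume: Volume,
    *,
    wiener: bool = True,
    wiener_kernel: tuple[int, int] = (5, 5),
    wiener_axis: int | str = "y",
    cap: bool = True,
    cap_k: float = 3.0,
    rescale: bool = True,
    nlm: bool = False,
    nlm_patch: int = 3,
    nlm_search: int = 7,
    nlm_h: float | None = None,
) -> Volume:
    """Run the conditioning chain in its canonical order.

    float conversion -> Wiener -> z-capping -> 16-bit rescale -> NLM.
    Steps can be disabled individually; the order is fixed.
    """
    out = volume.astype_float()
    if wiener:
        out = wiener_slice_filter(out, wiener_kernel, wiener_axis)
    if cap:
        out = cap_outliers_z(out, cap_k)
    if rescale:
        out = rescale_16bit(out)
    if nlm:
        out = nlm_denoise(out, nlm_patch, nlm_search, nlm_h)
    return out
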