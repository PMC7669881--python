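"""Full-width-at-half-maximum vessel diameter estimation.

A vessel appears in an OCT angiography cross-section as a dark dip in
the intensity profile taken perpendicular to its axis.  The estimator:

1. samples the image along 7 parallel lines (the probe plus three
   unit-spaced offsets on each side) and averages them pointwise;
2. resamples the averaged profile to 100 points with a natural cubic
   spline;
3. locates a region of interest (ROI) around the dip: the nearest
   local minimum outside the maximum edge point on each side, falling
   back to the steepest point beyond the maximum, then to the profile
   end;
4. finds the landmark set inside the ROI: the darkest value b2 in the
   vessel, the brightest values b1/b3 outside it on each side, the
   steepest wall positions a1/a2, the half-maximum thresholds
   c1 = (b1+b2)/2 and c2 = (b2+b3)/2, and the threshold crossings
   h1/h2 localized by linear interpolation;
5. reports d = h2 - h1 (the full width at half maximum), the outer
   diameter estimate D_FWHM = d * sqrt(4/3), and the largest plausible
   outer diameter D_edge = distance between the two maxima.

Also provides the generic line-length measurement used for red blood
cell axes in histology images and a mean +/- population-SD summary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import map_coordinates

__all__ = [
    "FWHM_TO_OUTER",
    "LineProbe",
    "IntensityProfile",
    "ProfileLandmarks",
    "DiameterResult",
    "SummaryStats",
    "extract_profile",
    "spline_resample",
    "find_roi",
    "find_landmarks",
    "compute_diameters",
    "measure_vessel",
    "measure_axis",
    "summarize",
]

#: Conversion from the FWHM of the dip to the estimated outer diameter.
FWHM_TO_OUTER = math.sqrt(4.0 / 3.0)


@dataclass(frozen=True)
class LineProbe:
    """A measurement line across a vessel in one 2D cross-section.

    ``p0``/``p1`` are (row, col) endpoints in 0-indexed voxel
    coordinates (pixel-center convention).  ``width`` parallel lines,
    offset perpendicular to the probe at unit voxel spacing, are
    averaged.  The probe must cross the vessel and extend beyond the
    largest expected diameter on both sides.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    width: int = 7

    def __post_init__(self) -> None:
        if tuple(self.p0) == tuple(self.p1):
            raise ValueError("probe endpoints must differ")
        if self.width < 1 or self.width % 2 == 0:
            raise ValueError("width must be an odd integer >= 1")


@dataclass
class IntensityProfile:
    """Positions (µm along the probe, strictly increasing) + intensities."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.positions.shape != self.intensities.shape or self.positions.ndim != 1:
            raise ValueError("positions and intensities must be equal-length 1D arrays")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class ProfileLandmarks:
    """Landmark set of one vessel dip (positions in µm, intensities in image units)."""

    roi: tuple[float, float]
    a1: float
    a2: float
    b1: tuple[float, float]  # (position, intensity) of left outside maximum
    b2: tuple[float, float]  # (position, intensity) of in-vessel minimum
    b3: tuple[float, float]  # (position, intensity) of right outside maximum
    c1: float
    c2: float
    h1: float
    h2: float


@dataclass(frozen=True)
class DiameterResult:
    """d (FWHM), D_FWHM = d*sqrt(4/3), D_edge (max-to-max), all in µm."""

    d: float
    d_fwhm: float
    d_edge: float


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float  # population SD (divisor n)
    n: int


def extract_profile(
    image: np.ndarray, probe: LineProbe, spacing_um: float = 1.0
) -> IntensityProfile:
    """Averaged intensity profile along a width-``probe.width`` line.

    The image is sampled by bilinear interpolation along the probe and
    along ``(width-1)/2`` unit-spaced parallel offsets on each side;
    samples are averaged pointwise.  Sample pitch along the probe is
    one voxel; positions are converted to µm via ``spacing_um``.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("extract_profile expects a 2D cross-section")
    p0 = np.asarray(probe.p0, dtype=np.float64)
    p1 = np.asarray(probe.p1, dtype=np.float64)
    direction = p1 - p0
    length = float(np.hypot(*direction))
    u = direction / length
    normal = np.array([-u[1], u[0]])

    n_samples = int(math.floor(length)) + 1
    t = np.linspace(0.0, length, n_samples)
    half = (probe.width - 1) // 2
    offsets = np.arange(-half, half + 1, dtype=np.float64)

    # sample coordinates: (offset, sample) grids of rows and cols
    rows = p0[0] + np.outer(np.ones_like(offsets), t * u[0]) + np.outer(offsets * normal[0], np.ones_like(t))
    cols = p0[1] + np.outer(np.ones_like(offsets), t * u[1]) + np.outer(offsets * normal[1], np.ones_like(t))
    eps = 1e-9
    if (
        rows.min() < -eps
        or cols.min() < -eps
        or rows.max() > img.shape[0] - 1 + eps
        or cols.max() > img.shape[1] - 1 + eps
    ):
        raise ValueError("probe (including parallel offsets) falls outside the image")
    samples = map_coordinates(img, [rows, cols], order=1, mode="nearest")
    return IntensityProfile(positions=t * spacing_um, intensities=samples.mean(axis=0))


def spline_resample(profile: IntensityProfile, n: int = 100) -> IntensityProfile:
    """Cubic spline through the profile, evaluated at ``n`` equal steps.

    Not-a-knot boundary conditions (the MATLAB/scipy default), so that
    polynomials of degree <= 3 are reproduced exactly; endpoints are
    interpolated exactly by construction.
    """
    if profile.n_points < 4:
        raise ValueError("spline resampling requires at least 4 points")
    spline = CubicSpline(profile.positions, profile.intensities, bc_type="not-a-knot")
    x = np.linspace(profile.positions[0], profile.positions[-1], n)
    y = spline(x)
    # interpolation constraint: endpoints reproduced exactly
    y[0] = profile.intensities[0]
    y[-1] = profile.intensities[-1]
    return IntensityProfile(positions=x, intensities=y)


def _local_minima(y: np.ndarray) -> np.ndarray:
    """Indices of interior local minima (strictly below at least one neighbor)."""
    idx = []
    for i in range(1, y.size - 1):
        if y[i] <= y[i - 1] and y[i] <= y[i + 1] and (y[i] < y[i - 1] or y[i] < y[i + 1]):
            idx.append(i)
    return np.asarray(idx, dtype=int)


def find_roi(profile: IntensityProfile) -> tuple[float, float]:
    """ROI enclosing the vessel dip.

    From the global interior minimum (vessel center), the maximum edge
    point on each side is the brightest sample between the center and
    that profile end; the ROI endpoint is the nearest local minimum
    beyond the maximum, falling back to the steepest point beyond it,
    then to the profile end.
    """
    y = profile.intensities
    x = profile.positions
    if y.size < 3:
        raise ValueError("profile too short")
    center = int(np.argmin(y[1:-1])) + 1
    if not (y[center] < y[:center].max() and y[center] < y[center + 1 :].max()):
        raise ValueError("no vessel dip detected (profile has no interior minimum)")

    left_max = int(np.argmax(y[: center + 1]))
    right_max = center + int(np.argmax(y[center:]))

    def outer_bound(max_idx: int, side: int) -> int:
        # side -1: search indices < max_idx (toward 0); +1: toward the end
        if side < 0:
            seg = np.arange(0, max_idx + 1)
        else:
            seg = np.arange(max_idx, y.size)
        minima = [i for i in _local_minima(y) if (i < max_idx if side < 0 else i > max_idx)]
        if minima:
            return min(minima, key=lambda i: abs(i - max_idx))
        # fallback: steepest point beyond the maximum
        if seg.size >= 2:
            dy = np.abs(np.diff(y[seg]))
            if dy.max() > 0:
                j = int(np.argmax(dy))
                # midpoint sample of the steepest interval, rounded outward
                return int(seg[j] if side < 0 else seg[j + 1])
        return 0 if side < 0 else y.size - 1

    left = outer_bound(left_max, -1)
    right = outer_bound(right_max, +1)
    return float(x[left]), float(x[right])


def _crossings(x: np.ndarray, y: np.ndarray, level: float) -> np.ndarray:
    """All positions where the piecewise-linear profile crosses ``level``."""
    out = []
    for i in range(y.size - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - level) * (y1 - level) < 0:
            out.append(x[i] + (level - y0) / (y1 - y0) * (x[i + 1] - x[i]))
        elif y0 == level and y1 != level:
            out.append(x[i])
    if y[-1] == level:
        out.append(x[-1])
    return np.asarray(out)


def find_landmarks(profile: IntensityProfile, roi: tuple[float, float]) -> ProfileLandmarks:
    """Landmark detection inside a ROI (see module docstring for the set)."""
    x = profile.positions
    y = profile.intensities
    lo, hi = roi
    mask = (x >= lo - 1e-12) & (x <= hi + 1e-12)
    if mask.sum() < 3:
        raise ValueError("ROI contains fewer than 3 samples")
    xi = x[mask]
    yi = y[mask]

    m = int(np.argmin(yi))
    if m == 0 or m == yi.size - 1:
        raise ValueError("ROI minimum lies on its boundary; no interior dip")
    b2 = (float(xi[m]), float(yi[m]))
    l_seg = slice(0, m + 1)
    r_seg = slice(m, yi.size)

    il = int(np.argmax(yi[l_seg]))
    ir = m + int(np.argmax(yi[r_seg]))
    b1 = (float(xi[il]), float(yi[il]))
    b3 = (float(xi[ir]), float(yi[ir]))

    # steepest points: extreme first difference on each wall segment,
    # ties broken toward the vessel center
    def steepest(seg: slice, descending: bool) -> float:
        ys = yi[seg]
        xs = xi[seg]
        if ys.size < 2:
            raise ValueError("wall segment too short for steepest-point search")
        d = np.diff(ys)
        scores = -d if descending else d
        best = np.flatnonzero(scores == scores.max())
        j = best[-1] if descending else best[0]
        return float(0.5 * (xs[j] + xs[j + 1]))

    a1 = steepest(l_seg, descending=True)
    a2 = steepest(r_seg, descending=False)

    c1 = 0.5 * (b1[1] + b2[1])
    c2 = 0.5 * (b2[1] + b3[1])

    # half-maximum crossings between each maximum and the vessel minimum;
    # with speckle there can be several -- take the one nearest the
    # corresponding maximum edge point (outer-diameter intent)
    lx = _crossings(xi[il : m + 1], yi[il : m + 1], c1)
    rx = _crossings(xi[m : ir + 1], yi[m : ir + 1], c2)
    if lx.size == 0 or rx.size == 0:
        raise ValueError("half-maximum threshold never crossed (flat dip)")
    h1 = float(lx[np.argmin(np.abs(lx - b1[0]))])
    h2 = float(rx[np.argmin(np.abs(rx - b3[0]))])

    return ProfileLandmarks(
        roi=(float(lo), float(hi)),
        a1=a1,
        a2=a2,
        b1=b1,
        b2=b2,
        b3=b3,
        c1=float(c1),
        c2=float(c2),
        h1=h1,
        h2=h2,
    )


def compute_diameters(landmarks: ProfileLandmarks) -> DiameterResult:
    """d = h2 - h1; D_FWHM = d * sqrt(4/3); D_edge = pos(b3) - pos(b1)."""
    d = landmarks.h2 - landmarks.h1
    return DiameterResult(
        d=d,
        d_fwhm=d * FWHM_TO_OUTER,
        d_edge=landmarks.b3[0] - landmarks.b1[0],
    )


def measure_vessel(
    image: np.ndarray,
    probe: LineProbe,
    spacing_um: float = 1.0,
    n_spline: int = 100,
) -> DiameterResult:
    """Full estimator: profile -> spline -> ROI -> landmarks -> diameters."""
    profile = spline_resample(extract_profile(image, probe, spacing_um), n_spline)
    roi = find_roi(profile)
    return compute_diameters(find_landmarks(profile, roi))


def measure_axis(
    p0: tuple[float, float],
    p1: tuple[float, float],
    spacing_um: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Euclidean length of a drawn line in µm, under per-axis pixel spacing."""
    d0 = (p1[0] - p0[0]) * spacing_um[0]
    d1 = (p1[1] - p0[1]) * spacing_um[1]
    return float(math.hypot(d0, d1))


def summarize(values) -> SummaryStats:
    """Mean and population SD (divisor n) of a list of measurements."""
    arr = np.asarray(list(values), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    return SummaryStats(mean=float(arr.mean()), sd=float(arr.std(ddof=0)), n=int(arr.size))
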