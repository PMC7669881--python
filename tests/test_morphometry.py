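"""FWHM diameter estimation: profiles, ROI, landmarks, diameters."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octavasc.morphometry import (
    FWHM_TO_OUTER,
    IntensityProfile,
    LineProbe,
    compute_diameters,
    extract_profile,
    find_landmarks,
    find_roi,
    measure_axis,
    measure_vessel,
    spline_resample,
    summarize,
)


def profile(y, x=None):
    y = np.asarray(y, dtype=float)
    x = np.arange(y.size, dtype=float) if x is None else np.asarray(x, dtype=float)
    return IntensityProfile(positions=x, intensities=y)


class TestExtractProfile:
    def test_uniform_image_flat_profile(self):
        img = np.full((20, 20), 42.0)
        p = extract_profile(img, LineProbe((10, 3), (10, 16)))
        np.testing.assert_allclose(p.intensities, 42.0)

    def test_seven_line_average_of_constant_rows(self):
        # rows 0..6 carry constants 0..6; a probe along row 3 averages to 3
        img = np.tile(np.arange(7.0)[:, None], (1, 12))
        p = extract_profile(img, LineProbe((3, 1), (3, 10)))
        np.testing.assert_allclose(p.intensities, 3.0, atol=1e-12)

    def test_dark_band_minimum_at_band_center(self):
        img = np.full((30, 40), 100.0)
        img[:, 18:23] = 0.0  # band center at column 20
        p = extract_profile(img, LineProbe((15, 4), (15, 36)), spacing_um=1.0)
        dark = p.positions[p.intensities == p.intensities.min()]
        assert abs((4 + dark.mean()) - 20) <= 1.0

    def test_positions_scaled_by_spacing(self):
        img = np.zeros((20, 20))
        p = extract_profile(img, LineProbe((10, 2), (10, 12)), spacing_um=2.5)
        assert p.positions[-1] == pytest.approx(10 * 2.5)

    def test_out_of_bounds_probe_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            extract_profile(img, LineProbe((1, 0), (1, 9)))  # offsets cross row -2
        with pytest.raises(ValueError):
            extract_profile(img, LineProbe((5, -2), (5, 8)))


class TestSplineResample:
    def test_linear_profile_stays_linear(self):
        p = profile(3.0 * np.arange(10) + 1.0)
        out = spline_resample(p, 100)
        np.testing.assert_allclose(out.intensities, 3.0 * out.positions + 1.0, atol=1e-9)

    def test_endpoints_reproduced(self, rng):
        p = profile(rng.normal(size=12))
        out = spline_resample(p, 100)
        assert out.intensities[0] == p.intensities[0]
        assert out.intensities[-1] == p.intensities[-1]
        assert out.n_points == 100

    def test_cubic_polynomial_reproduced(self):
        x = np.linspace(0, 5, 25)
        y = 2 * x**3 - 3 * x**2 + x - 7
        out = spline_resample(profile(y, x), 100)
        expected = 2 * out.positions**3 - 3 * out.positions**2 + out.positions - 7
        np.testing.assert_allclose(out.intensities, expected, atol=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spline_resample(profile([1.0, 2.0, 1.0]), 100)


def roi_oracle(y):
    """Exhaustive-scan implementation of the ROI rule (independent)."""
    n = len(y)
    center = 1 + int(np.argmin(y[1:-1]))
    if not (y[center] < max(y[:center]) and y[center] < max(y[center + 1 :])):
        raise ValueError("no dip")
    lmax = int(np.argmax(y[: center + 1]))
    rmax = center + int(np.argmax(y[center:]))

    def is_lmin(i):
        return (
            0 < i < n - 1
            and y[i] <= y[i - 1]
            and y[i] <= y[i + 1]
            and (y[i] < y[i - 1] or y[i] < y[i + 1])
        )

    left_candidates = [i for i in range(lmax) if is_lmin(i)]
    if left_candidates:
        left = max(left_candidates)  # nearest below lmax
    else:
        diffs = [abs(y[i + 1] - y[i]) for i in range(lmax)]
        left = int(np.argmax(diffs)) if diffs and max(diffs) > 0 else 0
    right_candidates = [i for i in range(rmax + 1, n) if is_lmin(i)]
    if right_candidates:
        right = min(right_candidates)
    else:
        diffs = [abs(y[i + 1] - y[i]) for i in range(rmax, n - 1)]
        right = rmax + 1 + int(np.argmax(diffs)) if diffs and max(diffs) > 0 else n - 1
    return left, right


def smooth_dip_profile(rng):
    """Random smooth profile with one clear central dip."""
    n = 100
    x = np.linspace(0, 1, n)
    base = 100 + np.cumsum(rng.normal(0, 0.8, n))
    from scipy.ndimage import gaussian_filter1d

    base = gaussian_filter1d(base, 4)
    depth = rng.uniform(40, 80)
    width = rng.uniform(0.05, 0.15)
    center = rng.uniform(0.35, 0.65)
    return base - depth * np.exp(-0.5 * ((x - center) / width) ** 2)


class TestFindRoi:
    def test_dip_with_outer_local_minima(self):
        # shoulder maxima at 5 and 11; nearest outer minima at 2 and 14
        y = np.array(
            [90, 85, 80, 85, 95, 100, 60, 10, 5, 10, 60, 100, 95, 85, 80, 85, 88, 90, 78, 92],
            dtype=float,
        )
        p = profile(y)
        left, right = find_roi(p)
        assert left == p.positions[2]
        assert right == p.positions[14]

    def test_no_outer_minimum_falls_back_to_steepest(self):
        # beyond the right maximum the profile falls monotonically (no
        # local minimum): the steepest point beyond it bounds the ROI
        y = np.array([50, 40, 100, 60, 10, 60, 100, 90, 80, 50, 45], dtype=float)
        p = profile(y)
        left, right = find_roi(p)
        assert right == pytest.approx(9.0)  # 80 -> 50 is the steepest drop
        assert left == p.positions[1]

    def test_monotone_profile_rejected(self):
        with pytest.raises(ValueError, match="no vessel dip"):
            find_roi(profile(np.linspace(0, 10, 20)))

    def test_matches_exhaustive_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(50):
            y = smooth_dip_profile(rng)
            p = profile(y)
            try:
                expected = roi_oracle(y)
            except ValueError:
                continue
            left, right = find_roi(p)
            assert (left, right) == (p.positions[expected[0]], p.positions[expected[1]])
            checked += 1
        assert checked >= 40  # the generator virtually always yields a dip


class TestFindLandmarks:
    def test_rectangular_well_fwhm_equals_width(self):
        y = np.full(21, 100.0)
        y[8:13] = 0.0
        p = profile(y)
        lm = find_landmarks(p, (0.0, 20.0))
        assert lm.c1 == lm.c2 == 50.0
        d = compute_diameters(lm)
        assert d.d == pytest.approx(5.0)  # crossings at 7.5 and 12.5

    def test_triangular_dip_crossing_at_half_width(self):
        # V dip from 100 to 0 over half-width 6
        w = 6
        y = np.concatenate(
            [np.full(5, 100.0), np.linspace(100, 0, w + 1), np.linspace(0, 100, w + 1)[1:], np.full(5, 100.0)]
        )
        p = profile(y)
        lm = find_landmarks(p, (0.0, float(y.size - 1)))
        d = compute_diameters(lm)
        assert d.d == pytest.approx(w, abs=1e-9)

    def test_asymmetric_shoulder_thresholds(self):
        y = np.concatenate(
            [np.full(4, 100.0), np.linspace(100, 20, 8), np.linspace(20, 60, 6), np.full(4, 60.0)]
        )
        p = profile(y)
        lm = find_landmarks(p, (0.0, float(y.size - 1)))
        assert lm.b1[1] == 100.0 and lm.b2[1] == 20.0 and lm.b3[1] == 60.0
        assert lm.c1 == 60.0 and lm.c2 == 40.0

    def test_flat_profile_rejected(self):
        y = np.full(15, 10.0)
        with pytest.raises(ValueError):
            find_landmarks(profile(y), (0.0, 14.0))


class TestComputeDiameters:
    @pytest.mark.parametrize("d, expected", [(6.6, 7.6), (24.7, 28.5)])
    def test_outer_diameter_from_fwhm(self, d, expected):
        assert round(d * FWHM_TO_OUTER, 1) == expected

    def test_degenerate_zero_width(self):
        from octavasc.morphometry import ProfileLandmarks

        lm = ProfileLandmarks(
            roi=(0, 10), a1=4, a2=6, b1=(2, 100), b2=(5, 0), b3=(8, 100),
            c1=50, c2=50, h1=5.0, h2=5.0,
        )
        res = compute_diameters(lm)
        assert res.d == 0.0 and res.d_fwhm == 0.0
        assert res.d_edge == 6.0

    def test_ratio_is_exact_algebraic_identity(self):
        from octavasc.morphometry import ProfileLandmarks

        lm = ProfileLandmarks(
            roi=(0, 30), a1=9, a2=21, b1=(5, 80), b2=(15, 10), b3=(25, 90),
            c1=45, c2=50, h1=9.3, h2=20.9,
        )
        res = compute_diameters(lm)
        assert res.d_fwhm / res.d == FWHM_TO_OUTER
        assert res.d <= res.d_edge


class TestMeasureVessel:
    def test_orientation_invariance(self, tube20):
        volume, _, _ = tube20
        section = volume.intensities[:, 24, :]
        fwd = measure_vessel(section, LineProbe((59.5, 20.0), (59.5, 140.0)))
        rev = measure_vessel(section, LineProbe((59.5, 140.0), (59.5, 20.0)))
        assert fwd.d == pytest.approx(rev.d, abs=1e-9)
        assert fwd.d_edge == pytest.approx(rev.d_edge, abs=1e-9)

    def test_d_not_larger_than_d_edge(self, tube20):
        volume, _, _ = tube20
        section = volume.intensities[:, 24, :]
        res = measure_vessel(section, LineProbe((59.5, 20.0), (59.5, 140.0)))
        assert res.d <= res.d_edge

    def test_recovers_true_diameter(self, tube20):
        volume, truth, _ = tube20
        section = volume.intensities[:, 24, :]
        res = measure_vessel(section, LineProbe((59.5, 20.0), (59.5, 140.0)))
        assert res.d == pytest.approx(truth.vessels[0].diameter_um, abs=1.0)


class TestMeasureAxis:
    def test_three_four_five(self):
        assert measure_axis((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_degenerate_zero_length(self):
        assert measure_axis((2, 2), (2, 2)) == 0.0

    def test_anisotropic_spacing(self):
        assert measure_axis((0, 0), (1, 1), spacing_um=(2.0, 1.0)) == pytest.approx(
            math.sqrt(5.0)
        )


class TestSummarize:
    def test_small_vessel_fwhm_column(self):
        stats = summarize([6.6, 9.4, 6.3, 5.7, 9.0, 5.6])
        assert round(stats.mean, 1) == 7.1
        assert round(stats.sd, 1) == 1.5

    def test_single_value(self):
        stats = summarize([4.2])
        assert stats.mean == 4.2 and stats.sd == 0.0 and stats.n == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_matches_two_pass_bruteforce(self, values):
        stats = summarize(values)
        mean = sum(values) / len(values)
        var = sum((v - mean) ** 2 for v in values) / len(values)
        assert stats.mean == pytest.approx(mean, abs=1e-6)
        assert stats.sd == pytest.approx(math.sqrt(var), abs=1e-6)
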