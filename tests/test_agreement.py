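import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivimwtt import (asymmetry_ratio, bland_altman, lin_ccc, linear_fit,
                     roi_mean, t2_threshold_loocv)


class TestRoiMean:
    def test_uniform_map(self):
        v, n = roi_mean(np.full((4, 4, 2), 50.0), np.ones((4, 4, 2), bool))
        assert v == 50.0 and n == 32

    def test_half_and_half(self):
        m = np.concatenate([np.full(8, 40.0), np.full(8, 60.0)])
        v, _ = roi_mean(m, np.ones(16, bool))
        assert v == 50.0

    def test_exclusion_reduces_count(self):
        vals = np.array([10.0, 10.0, 10.0, 99.0, 99.0, 99.0])
        excl = np.array([False, False, False, True, True, True])
        v, n = roi_mean(vals, np.ones(6, bool), excl)
        assert v == 10.0 and n == 3

    def test_zero_survivors_flagged(self):
        v, n = roi_mean(np.ones(4), np.zeros(4, bool))
        assert np.isnan(v) and n == 0


class TestAsymmetry:
    @pytest.mark.parametrize("l,r,expect", [(2, 2, 1.0), (3, 2, 1.5)])
    def test_ratio(self, l, r, expect):
        assert asymmetry_ratio(l, r) == expect

    def test_zero_denominator_missing(self):
        assert np.isnan(asymmetry_ratio(2.0, 0.0))


class TestLinCCC:
    def test_perfect_concordance(self):
        x = np.arange(10.0)
        ccc, _ = lin_ccc(x, x)
        assert ccc == pytest.approx(1.0)

    def test_location_shift_closed_form(self):
        x = np.arange(10.0)
        c = 3.0
        ccc, _ = lin_ccc(x, x + c)
        assert ccc == pytest.approx(2 * x.var() / (2 * x.var() + c**2), rel=1e-12)

    def test_perfect_discordance(self):
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        ccc, _ = lin_ccc(x, -x)
        assert ccc == pytest.approx(-1.0)

    def test_degenerate_input_flagged(self):
        ccc, _ = lin_ccc(np.full(5, 2.0), np.full(5, 2.0))
        assert np.isnan(ccc)

    def test_ccc_equals_pearson_when_moments_match(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 500)
        y = 0.6 * x + rng.normal(0, 0.8, 500)
        y = (y - y.mean()) / y.std() * x.std() + x.mean()   # match moments
        ccc, _ = lin_ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert ccc == pytest.approx(r, abs=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_ccc_bounded_by_pearson(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 2, 40)
        ccc, _ = lin_ccc(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert -1 - 1e-12 <= ccc <= 1 + 1e-12
        assert abs(ccc) <= abs(r) + 1e-12

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        x = rng.normal(50, 10, 60)
        y = x + rng.normal(0, 5, 60)
        ccc, (lo, hi) = lin_ccc(x, y)
        assert lo < ccc < hi
        assert -1 <= lo and hi <= 1


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.arange(5.0)
        mean, (lo, hi), _ = bland_altman(x, x)
        assert mean == 0.0 and lo == 0.0 and hi == 0.0

    def test_hand_computed_three_points(self):
        x = np.array([0.0, 1.0, 2.0])
        y = np.array([1.0, 1.0, 1.0])   # d = (-1, 0, 1), sd = 1
        mean, (lo, hi), stable = bland_altman(x, y)
        assert mean == 0.0
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)
        assert stable

    def test_constant_offset(self):
        x = np.arange(4.0)
        mean, (lo, hi), _ = bland_altman(x + 2.5, x)
        assert mean == pytest.approx(2.5)
        assert lo == pytest.approx(2.5) and hi == pytest.approx(2.5)

    def test_small_n_flagged_unstable(self):
        _, _, stable = bland_altman(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        assert not stable

    def test_limits_cover_95pct_of_gaussian_differences(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, 20000)
        y = x + rng.normal(0.5, 2.0, 20000)
        mean, (lo, hi), _ = bland_altman(x, y)
        d = x - y
        coverage = np.mean((d >= lo) & (d <= hi))
        assert coverage >= 0.93


class TestLinearFit:
    def test_exact_line(self):
        x = np.arange(5.0)
        slope, intercept, r2 = linear_fit(x, 2 * x + 1)
        assert (slope, intercept, r2) == (2.0, 1.0, 1.0)

    def test_null_relationship(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 10 ** 4)
        y = rng.normal(0, 1, 10 ** 4)
        _, _, r2 = linear_fit(x, y)
        assert r2 < 0.01

    def test_zero_x_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            linear_fit(np.ones(5), np.arange(5.0))


class TestT2ThresholdLOOCV:
    def test_separable_returns_gap_midpoint(self):
        thr, acc, reliable = t2_threshold_loocv(
            [80.0, 90.0, 100.0, 1500.0, 2000.0],
            [False, False, False, True, True])
        assert thr == 800.0
        assert acc == 1.0 and reliable

    def test_interleaved_unreliable(self):
        # CSF interleaved below/above tissue: no cut beats chance
        t2 = [100.0, 200.0, 300.0, 400.0]
        labels = [True, False, True, False]
        _, acc, reliable = t2_threshold_loocv(t2, labels)
        assert acc <= 0.5
        assert not reliable

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            t2_threshold_loocv([1.0, 2.0, 3.0], [False, False, True])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both"):
            t2_threshold_loocv([1.0, 2.0, 3.0, 4.0], [False] * 4)

    def test_tie_breaks_toward_higher_threshold(self):
        # two equally perfect gaps cannot exist; equal-accuracy candidates within
        # one gap resolve to the higher midpoint
        thr, acc, _ = t2_threshold_loocv(
            [10.0, 20.0, 1000.0, 2000.0], [False, False, True, True])
        assert acc == 1.0
        assert thr == 510.0   # midpoint of the separating gap
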