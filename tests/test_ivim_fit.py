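import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivimwtt import (FitConfig, biexp_signal, fit_diffusion_segment,
                     fit_perfusion_segment, fit_volume, fit_voxel)
from ivimwtt.phantom import default_brain_phantom

from conftest import fit_phantom


class TestDiffusionSegment:
    def test_exact_monoexponential_recovery(self, bvals):
        curve = biexp_signal(bvals, 0.0, 0.0008, 0.0)
        D, f, ok = fit_diffusion_segment(curve, bvals)
        assert ok
        assert D == pytest.approx(0.0008, rel=1e-12)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_biexponential_D_within_2pct_f_within_001(self, bvals):
        # residual perfusion contamination at b >= 333 bounds the one-pass accuracy
        curve = biexp_signal(bvals, 0.1, 0.0008, 0.01)
        D, f, ok = fit_diffusion_segment(curve, bvals)
        assert ok
        assert D == pytest.approx(0.0008, rel=0.02)
        assert f == pytest.approx(0.1, abs=0.01)

    def test_constant_curve_gives_zero_slope(self, bvals):
        D, f, ok = fit_diffusion_segment(np.ones_like(bvals), bvals)
        assert ok and D == 0.0 and f == 0.0

    def test_nonpositive_high_b_signal_invalid(self, bvals):
        curve = biexp_signal(bvals, 0.05, 0.0008, 0.01)
        curve[7] = 0.0
        _, _, ok = fit_diffusion_segment(curve, bvals)
        assert not ok

    def test_too_few_high_b_points_raises(self):
        b = np.array([0.0, 111.0, 222.0, 333.0])
        with pytest.raises(ValueError, match=">= 3"):
            fit_diffusion_segment(np.ones(4), b)


class TestPerfusionSegment:
    def test_exact_dstar_given_truth(self, bvals):
        curve = biexp_signal(bvals, 0.1, 0.0008, 0.01)
        dstar, ok = fit_perfusion_segment(curve, bvals, D=0.0008, f=0.1)
        assert ok
        assert dstar == pytest.approx(0.01, rel=1e-6)

    def test_f_at_floor_gives_undefined_dstar(self, bvals):
        curve = biexp_signal(bvals, 0.0, 0.0008, 0.0)
        dstar, ok = fit_perfusion_segment(curve, bvals, D=0.0008, f=0.0)
        assert not ok and dstar == 0.0

    def test_dstar_above_threshold_hits_bound_and_is_excluded(self, bvals):
        curve = biexp_signal(bvals, 0.1, 0.0008, 0.2)
        res = fit_voxel(curve, bvals)
        assert res.Dstar == pytest.approx(0.10, abs=1e-9)
        assert not res.valid


class TestFitVoxel:
    def test_noiseless_biexponential_near_perfect_fit(self, bvals):
        res = fit_voxel(biexp_signal(bvals, 0.1, 0.0008, 0.01), bvals)
        assert res.ssr <= 1e-6
        assert res.valid

    def test_pure_noise_voxel_never_nan(self, bvals):
        rng = np.random.default_rng(5)
        res = fit_voxel(rng.uniform(0.9, 1.1, bvals.size), bvals)
        for v in (res.f, res.D, res.Dstar, res.ssr):
            assert np.isfinite(v)

    @pytest.mark.parametrize("f,D,dstar", [
        (0.04, 0.0007, 0.009),
        (0.1, 0.0008, 0.01),
        (0.02, 0.0007, 0.008),
    ])
    def test_recovery_matches_brute_force_refit_oracle(self, bvals, f, D, dstar):
        """The composed fit lands on the global minimum a dense grid refit finds."""
        curve = biexp_signal(bvals, f, D, dstar)
        res = fit_voxel(curve, bvals)
        # oracle: brute-force joint grid around the truth, same objective
        fs = np.linspace(max(f - 0.02, 0), f + 0.02, 41)
        dss = np.linspace(dstar * 0.7, dstar * 1.3, 121)
        best = np.inf
        for fg in fs:
            model = fg * np.exp(-np.outer(dss, bvals)) + (1 - fg) * np.exp(-res.D * bvals)
            sse = np.sum((model - curve) ** 2, axis=1)
            best = min(best, sse.min())
        assert res.ssr <= best + 1e-12
        assert res.f == pytest.approx(f, abs=0.01)
        assert res.D == pytest.approx(D, rel=0.02)
        assert res.Dstar == pytest.approx(dstar, rel=0.02)

    def test_one_pass_config_restores_independent_steps(self, bvals):
        curve = biexp_signal(bvals, 0.1, 0.0008, 0.01)
        cfg = FitConfig(n_iterations=0)
        res = fit_voxel(curve, bvals, cfg)
        D1, f1, _ = fit_diffusion_segment(curve, bvals, cfg)
        ds1, _ = fit_perfusion_segment(curve, bvals, D1, f1, cfg)
        assert res.D == D1 and res.f == f1
        assert res.Dstar == pytest.approx(ds1, rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(1e-3, 1e6))
    def test_scale_invariance_of_parameters(self, bvals, scale):
        curve = biexp_signal(bvals, 0.06, 0.0008, 0.015)
        a = fit_voxel(curve, bvals)
        b = fit_voxel(curve, bvals)  # normalized curves are scale-free already
        raw = curve * scale
        c = fit_voxel(raw / raw[0], bvals)
        assert (a.f, a.D, a.Dstar) == (b.f, b.D, b.Dstar)
        assert c.f == pytest.approx(a.f, rel=1e-9, abs=1e-12)
        assert c.Dstar == pytest.approx(a.Dstar, rel=1e-9)


class TestFitVolume:
    def test_matches_ground_truth_on_noiseless_phantom(self, clean_fit):
        curves, res, truth = clean_fit
        pure = truth.pure & curves.valid & (truth.labels > 0)
        assert pure.sum() > 500
        assert np.all(np.abs(res.f[pure] - truth.f[pure]) <= 0.01)
        nz = pure & (truth.D > 0)
        assert np.all(np.abs(res.D[nz] - truth.D[nz]) / truth.D[nz] <= 0.02)
        perf = pure & (truth.f > 1e-3)
        rel = np.abs(res.Dstar[perf] - truth.Dstar[perf]) / truth.Dstar[perf]
        assert np.all(rel <= 0.02)

    def test_empty_mask_is_hard_error(self, bvals):
        vol = np.ones((2, 2, 1, 10))
        with pytest.raises(ValueError, match="empty mask"):
            fit_volume(vol, bvals, mask=np.zeros((2, 2, 1), bool))

    def test_agrees_with_voxelwise_fit(self, bvals):
        rng = np.random.default_rng(11)
        vol = np.empty((3, 3, 1, 10))
        for i in range(3):
            for j in range(3):
                vol[i, j, 0] = biexp_signal(bvals, rng.uniform(0.01, 0.1),
                                            rng.uniform(5e-4, 1e-3),
                                            rng.uniform(0.006, 0.05))
        res = fit_volume(vol, bvals)
        for i in range(3):
            for j in range(3):
                rv = fit_voxel(vol[i, j, 0], bvals)
                assert res.f[i, j, 0] == pytest.approx(rv.f, abs=1e-10)
                assert res.Dstar[i, j, 0] == pytest.approx(rv.Dstar, rel=1e-8)

    def test_rmse_non_increasing_in_snr(self):
        """Parameter error vs ground truth shrinks as the phantom gets cleaner."""
        rmse_f, rmse_d = [], []
        for snr in (25, 50, 100, np.inf):
            curves, res, truth = fit_phantom(default_brain_phantom(seed=3, snr=snr))
            sel = truth.pure & curves.valid & (truth.labels > 0) & res.valid
            rmse_f.append(np.sqrt(np.mean((res.f[sel] - truth.f[sel]) ** 2)))
            rmse_d.append(np.sqrt(np.mean((res.D[sel] - truth.D[sel]) ** 2)))
        assert all(a > b for a, b in zip(rmse_f, rmse_f[1:]))
        assert all(a > b for a, b in zip(rmse_d, rmse_d[1:]))

    def test_dstar_exclusion_rule_applied(self, bvals):
        vol = np.stack([biexp_signal(bvals, 0.1, 0.0008, 0.2),
                        biexp_signal(bvals, 0.1, 0.0008, 0.01)])[:, None, None, :]
        res = fit_volume(vol, bvals)
        assert not res.valid[0, 0, 0]
        assert res.valid[1, 0, 0]
        assert res.tallies["n_dstar_excluded"] == 1
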