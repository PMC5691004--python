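import warnings

import numpy as np
import pytest

from cbctshade.bias_estimation import (BiasField, BiasProvenance,
                                       CorrectionConfig, FitDegenerateError,
                                       _ring_profile_bias, angular_median,
                                       estimate_slice_bias, fit_polynomial_1d,
                                       precorrect_global_radial, radial_median,
                                       smooth_bias_3d)
from cbctshade.phantom_sim import (PhantomSpec, ShadingModel, apply_shading,
                                   make_bias_field, make_phantom)
from cbctshade.polar_geometry import PolarSlice
from cbctshade.volume_io import hu_to_rel_mu


def make_polar(values, valid=None, radial_step=0.25):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return PolarSlice(values=values, radial_step=radial_step,
                      center_xy=(32.0, 32.0), valid=valid)


class TestCorrectionConfig:
    def test_defaults_match_published_parameters(self):
        cfg = CorrectionConfig()
        assert cfg.bone_threshold == 100.0
        assert cfg.gas_range == (-750.0, -500.0)
        assert cfg.n_radial == 600 and cfg.n_angular == 360
        assert cfg.angular_width_deg == 80.0
        assert cfg.radial_width_bins == 1
        assert cfg.order_angular == 8 and cfg.order_radial == 3

    @pytest.mark.parametrize("bad", [
        {"order_angular": -1},
        {"angular_width_deg": 0.5},
        {"angular_width_deg": 400.0},
        {"radial_width_bins": 0},
        {"median3d_kernel": (2, 3, 3)},
        {"clamp_lo": 0.0},
        {"clamp_lo": 6.0, "clamp_hi": 5.0},
        {"downsample_factor": 0},
        {"gas_range": (-500.0, -750.0)},
        {"angular_fit_axis": "diagonal"},
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ValueError):
            CorrectionConfig(**bad)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CorrectionConfig.from_dict({"bogus": 1})

    def test_yaml_round_trip(self, tmp_path):
        cfg = CorrectionConfig(angular_width_deg=40.0, precorrection=True)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = CorrectionConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg


class TestAngularMedian:
    def test_constant_field(self):
        p = make_polar(np.full((40, 36), 2.5))
        med, valid = angular_median(p, 80.0)
        np.testing.assert_allclose(med, 2.5)
        assert valid.all()

    def test_full_circle_of_1_to_360(self):
        vals = np.tile(np.arange(1.0, 361.0)[None, :], (5, 1))
        med, _ = angular_median(make_polar(vals), 360.0)
        np.testing.assert_allclose(med, 180.5)

    def test_invalid_bins_excluded(self):
        vals = np.array([[1.0, 2.0, 3.0, 1000.0]])
        valid = np.array([[True, True, True, False]])
        med, mvalid = angular_median(make_polar(vals, valid), 360.0)
        np.testing.assert_allclose(med, 2.0)
        assert mvalid.all()

    def test_all_invalid_window_flagged(self):
        vals = np.ones((3, 8))
        valid = np.zeros((3, 8), bool)
        med, mvalid = angular_median(make_polar(vals, valid), 90.0)
        assert not mvalid.any()

    def test_matches_nanmedian_oracle(self, rng):
        vals = rng.normal(0, 1, (30, 36))
        valid = rng.random((30, 36)) > 0.3
        p = make_polar(vals, valid)
        med, mvalid = angular_median(p, 80.0)
        # independent brute-force: explicit circular window + nanmedian
        w = round(80.0 / p.angular_step_deg)
        offs = np.arange(w) - w // 2
        masked = np.where(valid, vals, np.nan)
        for r in range(30):
            for t in range(36):
                win = masked[r, (t + offs) % 36]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    expect = np.nanmedian(win)
                if np.isnan(expect):
                    assert not mvalid[r, t]
                else:
                    assert med[r, t] == pytest.approx(expect, abs=1e-12)

    def test_circular_wrap(self):
        # a lone invalid bin at angle 0: window for the last angle must wrap
        vals = np.tile(np.arange(8.0)[None, :], (2, 1))
        med, _ = angular_median(make_polar(vals), 360.0 * 3 / 8)
        # window of 3 at angle 7 wraps to {6, 7, 0}
        assert med[0, 7] == pytest.approx(np.median([6.0, 7.0, 0.0]))

    def test_scale_equivariance(self, rng):
        vals = np.abs(rng.normal(1, 0.2, (20, 36)))
        valid = rng.random((20, 36)) > 0.2
        m1, _ = angular_median(make_polar(vals, valid), 80.0)
        m2, _ = angular_median(make_polar(3.0 * vals, valid), 80.0)
        np.testing.assert_allclose(m2, 3.0 * m1)


class TestRadialMedian:
    def test_width_one_is_identity(self, rng):
        vals = rng.normal(0, 1, (20, 8))
        valid = rng.random((20, 8)) > 0.1
        out, ov = radial_median(vals, valid, 1)
        np.testing.assert_array_equal(out, vals)
        np.testing.assert_array_equal(ov, valid)

    def test_width_three_median(self):
        vals = np.array([[0.0], [10.0], [1.0], [2.0], [3.0]])
        valid = np.ones_like(vals, bool)
        out, _ = radial_median(vals, valid, 3)
        np.testing.assert_allclose(out[:, 0], [5.0, 1.0, 2.0, 2.0, 2.5])


class TestFitPolynomial1D:
    def test_exact_cubic(self):
        x = np.linspace(-1, 1, 50)
        y = 2.0 - x + 0.5 * x ** 2 + 3.0 * x ** 3
        fit = fit_polynomial_1d(y, np.ones(50, bool), 3)
        np.testing.assert_allclose(fit, y, atol=1e-9)

    def test_order_zero_is_mean_of_valid(self, rng):
        y = rng.normal(5, 1, 40)
        valid = rng.random(40) > 0.4
        fit = fit_polynomial_1d(y, valid, 0)
        np.testing.assert_allclose(fit, y[valid].mean())

    def test_matches_normal_equations_oracle(self):
        n, order = 120, 8
        x = np.linspace(-1, 1, n)
        y = 1.0 + 0.3 * x ** 3 + 0.2 * np.sin(4 * x)
        valid = np.ones(n, bool)
        valid[40:55] = False
        fit = fit_polynomial_1d(y, valid, order)
        # independent direct solve of the normal equations
        V = np.vander(x[valid], order + 1, increasing=True)
        coeffs = np.linalg.solve(V.T @ V, V.T @ y[valid])
        expect = np.vander(x, order + 1, increasing=True) @ coeffs
        np.testing.assert_allclose(fit, expect, atol=1e-6)

    def test_extrapolates_to_invalid_positions(self):
        x = np.linspace(-1, 1, 30)
        y = 1.0 + 2.0 * x
        valid = x < 0.5
        fit = fit_polynomial_1d(y, valid, 1)
        np.testing.assert_allclose(fit, y, atol=1e-9)

    def test_degenerate_raises(self):
        y = np.arange(10.0)
        valid = np.zeros(10, bool)
        valid[3] = True
        with pytest.raises(FitDegenerateError):
            fit_polynomial_1d(y, valid, 3)


class TestEstimateSliceBias:
    def cfg(self, **kw):
        kw.setdefault("n_radial", 200)
        kw.setdefault("n_angular", 180)
        return CorrectionConfig(**kw)

    def test_uniform_body_gives_identity_bias(self):
        valid = np.zeros((200, 180), bool)
        valid[:120] = True
        p = make_polar(np.ones((200, 180)), valid)
        bias = estimate_slice_bias(p, self.cfg())
        assert np.abs(bias[valid] - 1.0).max() < 1e-6

    def test_separable_smooth_field_recovered(self):
        n_r, n_a = 200, 180
        r = np.linspace(0, 1, n_r)[:, None]
        theta = np.deg2rad((np.arange(n_a) + 0.5) * 2.0)[None, :]
        f = 1.0 - 0.25 * r + 0.1 * r ** 2 - 0.05 * r ** 3
        g = 1.0 + 0.1 * np.cos(theta)
        field = f * g
        valid = np.zeros((n_r, n_a), bool)
        valid[:160] = True
        p = make_polar(field, valid)
        bias = estimate_slice_bias(p, self.cfg())
        rel = (bias[valid] - field[valid]) / field[valid]
        assert np.sqrt((rel ** 2).mean()) < 0.02

    def test_flagged_wedge_does_not_perturb_bias(self):
        n_r, n_a = 200, 180
        r = np.linspace(0, 1, n_r)[:, None]
        base = np.tile(1.0 - 0.2 * r, (1, n_a))
        valid = np.zeros((n_r, n_a), bool)
        valid[:150] = True
        clean = estimate_slice_bias(make_polar(base.copy(), valid.copy()),
                                    self.cfg())
        wedge = base.copy()
        wvalid = valid.copy()
        wedge[30:60, 40:60] = 9.0       # high-intensity wedge ...
        wvalid[30:60, 40:60] = False    # ... flagged invalid
        with_wedge = estimate_slice_bias(make_polar(wedge, wvalid), self.cfg())
        assert np.abs(clean - with_wedge).max() < 1e-6

    def test_no_valid_bins_returns_identity(self):
        p = make_polar(np.ones((50, 36)), np.zeros((50, 36), bool))
        bias = estimate_slice_bias(p, CorrectionConfig(n_radial=50, n_angular=36))
        np.testing.assert_allclose(bias, 1.0)

    def test_scale_equivariance(self, rng):
        n_r, n_a = 100, 90
        vals = np.abs(1.0 + 0.1 * rng.normal(size=(n_r, n_a)))
        valid = np.zeros((n_r, n_a), bool)
        valid[:70] = True
        cfg = CorrectionConfig(n_radial=n_r, n_angular=n_a)
        b1 = estimate_slice_bias(make_polar(vals, valid.copy()), cfg)
        b2 = estimate_slice_bias(make_polar(2.0 * vals, valid.copy()), cfg)
        np.testing.assert_allclose(b2, 2.0 * b1, rtol=1e-9)

    def test_strictly_positive_output(self, rng):
        vals = rng.normal(0, 0.01, (100, 90))  # near-zero field
        valid = np.ones((100, 90), bool)
        bias = estimate_slice_bias(make_polar(vals, valid),
                                   CorrectionConfig(n_radial=100, n_angular=90))
        assert bias.min() > 0


class TestRingProfileBias:
    def cfg(self):
        return CorrectionConfig()

    def test_ramp_profile_follows_the_rule(self):
        # 1.0 for r < 200, linear down to 0.7 by r = 240, 0.7 beyond
        profile = np.ones(600)
        profile[200:240] = np.linspace(1.0, 0.7, 41)[:-1]
        profile[240:] = 0.7
        defined = np.ones(600, bool)
        bias = _ring_profile_bias(profile, defined, self.cfg())
        assert bias is not None
        np.testing.assert_allclose(bias[:195], 1.0)
        np.testing.assert_allclose(bias[246:], 0.7)
        # inside the detected band the profile itself is preserved
        np.testing.assert_allclose(bias[205:235], profile[205:235])

    def test_constant_profile_gives_identity(self):
        bias = _ring_profile_bias(np.ones(600), np.ones(600, bool), self.cfg())
        assert bias is None

    def test_normalized_to_inner_level(self):
        profile = np.full(600, 0.8)
        profile[300:320] = np.linspace(0.8, 0.6, 20)
        profile[320:] = 0.6
        bias = _ring_profile_bias(profile, np.ones(600, bool), self.cfg())
        np.testing.assert_allclose(bias[:295], 1.0)
        np.testing.assert_allclose(bias[325:], 0.75)  # 0.6 / 0.8


class TestPrecorrectGlobalRadial:
    def test_ring_phantom_error_reduced(self):
        spec = PhantomSpec(grid_shape=(2, 128, 128), spacing=(2.8, 2.8, 2.8),
                           body_semi_axes_mm=(150.0, 130.0))
        truth, labels = make_phantom(spec)
        # ring shading darkens the periphery; the inner region is clean, so
        # the inner-normalized precorrection restores absolute levels too
        model = ShadingModel(kind="GLOBAL_RING", amplitude=0.25,
                             ring_inner_mm=55.0, ring_outer_mm=95.0,
                             inner_level=1.0, outer_level=0.75)
        bias = make_bias_field(model, truth)
        shaded = apply_shading(truth, bias, 0.0, 0)
        rel = hu_to_rel_mu(shaded)
        cfg = CorrectionConfig(precorrection=True, n_radial=300, n_angular=180,
                               downsample_factor=1)
        pre, field = precorrect_global_radial(rel, cfg)
        body = labels > 0
        err_before = np.abs(1000.0 * (rel.values - 1.0))[body].mean()
        err_after = np.abs(1000.0 * (pre.values - 1.0))[body].mean()
        assert err_after < err_before / 3.0
        assert field.provenance is BiasProvenance.PRECORRECTION

    def test_uniform_volume_identity(self):
        spec = PhantomSpec(grid_shape=(1, 64, 64), spacing=(2.8, 2.8, 2.8),
                           body_semi_axes_mm=(70.0, 60.0))
        truth, _ = make_phantom(spec)
        rel = hu_to_rel_mu(truth)
        cfg = CorrectionConfig(precorrection=True, n_radial=200, n_angular=180)
        pre, field = precorrect_global_radial(rel, cfg)
        np.testing.assert_allclose(field.values, 1.0)
        np.testing.assert_array_equal(pre.values, rel.values)


class TestSmoothBias3D:
    def test_constant_unchanged(self):
        stack = np.full((5, 10, 10), 1.3)
        np.testing.assert_allclose(smooth_bias_3d(stack), 1.3)

    def test_spike_removed(self):
        stack = np.ones((5, 9, 9))
        stack[2, 4, 4] = 4.0
        out = smooth_bias_3d(stack, (3, 3, 3))
        np.testing.assert_allclose(out, 1.0)

    def test_matches_brute_force_sort_oracle(self, rng):
        stack = rng.uniform(0.5, 2.0, (7, 7, 7))
        out = smooth_bias_3d(stack, (3, 3, 3), clamp=(0.01, 10.0))
        for _ in range(10):
            i, j, k = rng.integers(1, 6, 3)
            nb = stack[i - 1:i + 2, j - 1:j + 2, k - 1:k + 2].ravel()
            expect = np.sort(nb)[13]  # middle of 27
            assert out[i, j, k] == pytest.approx(expect)

    def test_clamped(self):
        stack = np.full((3, 9, 9), 10.0)
        out = smooth_bias_3d(stack, clamp=(0.2, 5.0))
        np.testing.assert_allclose(out, 5.0)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            smooth_bias_3d(np.ones((3, 9, 9)), (2, 3, 3))


def test_bias_field_must_be_positive():
    with pytest.raises(ValueError, match="positive"):
        BiasField(values=np.zeros((2, 4, 4)), provenance=BiasProvenance.MAIN)
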