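"""Inverse solver: exact recovery, identifiability, uncertainties, pooling."""

import numpy as np
import pytest

from sbdot import (
    DiffusionForward,
    EllipsoidZone,
    MeasurementFrame,
    OpticalProperties,
    ReconstructionConfig,
    SceneModel,
    ShapeFit,
    combine_wavelengths,
    fit,
    sensitivity_sweep,
)
from conftest import AGAR_750, COAG_PROPS, noisy_frame


@pytest.fixture(scope="module")
def template(small_zone_scene):
    """Fit template starting away from the truth (a=8, b=8)."""
    return small_zone_scene.with_params(a=5.0, b=5.0)


class TestExactRecovery:
    def test_noiseless_recovery_within_rasterization_tolerance(
            self, small_zone_frame, template, layout):
        res = fit(small_zone_frame, template, layout)
        assert res.converged
        assert res.params["a"] == pytest.approx(8.0, abs=0.2)
        assert res.params["b"] == pytest.approx(8.0, abs=0.2)
        assert res.params["zone_mua"] == pytest.approx(COAG_PROPS.mua, rel=0.02)
        assert res.params["zone_musp"] == pytest.approx(COAG_PROPS.musp, rel=0.02)

    @pytest.mark.parametrize("a0", [2.0, 6.0, 12.0])
    def test_recovery_from_any_initial_radius(self, small_zone_frame, template,
                                              layout, a0):
        cfg = ReconstructionConfig(initial={"a": a0})
        res = fit(small_zone_frame, template, layout, cfg)
        assert res.params["a"] == pytest.approx(8.0, abs=0.2)

    def test_determinism_bitwise(self, small_zone_frame, template, layout):
        r1 = fit(small_zone_frame, template, layout)
        r2 = fit(small_zone_frame, template, layout)
        assert r1.params == r2.params
        assert r1.cost_path == r2.cost_path

    def test_cost_nonincreasing_over_accepted_iterations(
            self, small_zone_frame, template, layout):
        res = fit(small_zone_frame, template, layout)
        assert all(c2 <= c1 for c1, c2 in zip(res.cost_path, res.cost_path[1:]))

    def test_noiseless_standard_errors_tiny(self, small_zone_frame, template, layout):
        res = fit(small_zone_frame, template, layout)
        assert res.bse["a"] <= 1e-3 * 8.0
        assert res.bse["zone_musp"] <= 1e-3 * COAG_PROPS.musp


class TestIdentifiability:
    def test_zero_contrast_flags_non_identifiable(self, fast_grid, layout):
        scene = SceneModel(background=AGAR_750,
                           zone=EllipsoidZone((0, 0, 12), 6, 6),
                           zone_props=AGAR_750, grid=fast_grid)
        pred = DiffusionForward(scene, layout).predict()
        frame = MeasurementFrame(0.0, 750.0, pred, calibrated=True)
        res = fit(frame, scene, layout)
        assert not res.identifiable
        # shape is unconstrained by a contrast-free frame
        bound_width = 15.0 - 1.0
        assert res.bse["a"] > bound_width / 4 or not np.isfinite(res.bse["a"])

    def test_no_valid_channels_is_an_error(self, small_zone_frame, template, layout):
        empty = small_zone_frame.replace(mask=np.zeros((8, 8), dtype=bool))
        with pytest.raises(ValueError, match="no valid channels"):
            ShapeFit(empty, template, layout)

    def test_initial_estimate_outside_bounds_rejected(self, small_zone_frame,
                                                      template, layout):
        cfg = ReconstructionConfig(initial={"a": 20.0})
        with pytest.raises(ValueError, match="bounds"):
            ShapeFit(small_zone_frame, template, layout, cfg)


class TestUncertainty:
    def test_bootstrap_zero_noise_sd_tiny(self, small_zone_frame, template, layout):
        model = ShapeFit(small_zone_frame, template, layout)
        base = model.fit()
        sd = base.bootstrap(n_rep=10, seed=1)
        assert sd["a"] <= 1e-3 * 8.0

    def test_hessian_se_within_factor_two_of_bootstrap(self, small_zone_scene,
                                                       layout):
        pred = DiffusionForward(small_zone_scene, layout).predict()
        frame = noisy_frame(pred, 0.01, seed=4)
        model = ShapeFit(frame, small_zone_scene.with_params(a=6.0, b=6.0), layout)
        base = model.fit()
        sd = base.bootstrap(n_rep=50, seed=2)
        assert sd["a"] / 2 <= base.bse["a"] <= sd["a"] * 2

    def test_se_scales_linearly_with_noise(self, small_zone_scene, layout):
        """Doubling the noise amplitude roughly doubles SE(a)."""
        pred = DiffusionForward(small_zone_scene, layout).predict()
        tmpl = small_zone_scene.with_params(a=6.0, b=6.0)
        ratios = []
        for seed in range(8):
            se = {}
            for sigma in (0.005, 0.01):
                res = fit(noisy_frame(pred, sigma, seed=100 + seed), tmpl, layout)
                se[sigma] = res.bse["a"]
            ratios.append(se[0.01] / se[0.005])
        assert 1.5 <= np.mean(ratios) <= 2.5

    def test_bootstrap_sd_stable_across_seeds(self, small_zone_scene, layout):
        pred = DiffusionForward(small_zone_scene, layout).predict()
        frame = noisy_frame(pred, 0.01, seed=9)
        model = ShapeFit(frame, small_zone_scene.with_params(a=6.0, b=6.0), layout)
        base = model.fit()
        sd1 = base.bootstrap(n_rep=50, seed=21)["a"]
        sd2 = base.bootstrap(n_rep=50, seed=22)["a"]
        assert abs(sd1 - sd2) / max(sd1, sd2) < 0.35

    def test_covariance_symmetric_psd(self, small_zone_frame, template, layout):
        res = fit(small_zone_frame, template, layout)
        cov = res.cov_params().to_numpy()
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) >= -1e-12 * np.abs(cov).max())


class TestSweep:
    def test_initialization_sweep_summary(self, small_zone_frame, template, layout):
        table, summary = sensitivity_sweep(
            small_zone_frame, template, layout, ReconstructionConfig(),
            initial_grids={"a": [4.0, 8.0, 12.0]})
        assert len(table) == 3
        assert summary["sd_a"] <= 0.2

    def test_fixed_offset_sweep_removes_param_from_fit(self, small_zone_frame,
                                                       small_zone_scene, layout):
        table, _ = sensitivity_sweep(
            small_zone_frame, small_zone_scene, layout, ReconstructionConfig(),
            fixed_offset_grids={"zone_mua": [-0.2, 0.0, 0.2]})
        assert len(table) == 3
        assert "fit_zone_mua" not in table.columns


class TestCombineWavelengths:
    def _result_with(self, frame, template, layout, a):
        res = fit(frame, template, layout)
        res.params["a"] = a
        return res

    def test_single_result_identity(self, small_zone_frame, template, layout):
        res = fit(small_zone_frame, template, layout)
        pooled = combine_wavelengths([res])
        assert pooled["a_mean"] == res.params["a"]
        assert pooled["a_sd"] == 0.0

    def test_three_wavelength_pooling(self, small_zone_frame, template, layout):
        rs = [self._result_with(small_zone_frame, template, layout, a)
              for a in (10.6, 10.8, 11.0)]
        pooled = combine_wavelengths(rs)
        assert pooled["a_mean"] == pytest.approx(10.8)
        assert pooled["a_sd"] == pytest.approx(0.2)

    def test_non_converged_excluded_with_warning(self, small_zone_frame,
                                                 template, layout):
        rs = [self._result_with(small_zone_frame, template, layout, a)
              for a in (10.0, 11.0, 12.0)]
        rs[2].converged = False
        with pytest.warns(UserWarning, match="non-converged"):
            pooled = combine_wavelengths(rs)
        assert pooled["n"] == 2
        assert pooled["a_mean"] == pytest.approx(10.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_wavelengths([])


class TestSummary:
    def test_summary_contains_parameters_and_distance(self, small_zone_frame,
                                                      template, layout):
        res = fit(small_zone_frame, template, layout)
        text = res.summary()
        assert "zone_musp" in text and "boundary-to-probe" in text
        assert f"{res.params['a']:.4g}"[:5] in text
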