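"""Synthetic generator: phantom scenes, treatment growth, noise, thermometry."""

import math

import numpy as np
import pytest

from sbdot import OpticalProperties, ProbeLayout
from sbdot.synth import (
    GrowthProtocol,
    NoiseModel,
    coagulated_from_native,
    extract_isotherm_radius,
    make_phantom_scene,
    make_temperature_map,
    simulate_treatment,
)

NATIVE = OpticalProperties(0.034, 0.66)


class TestPhantomScene:
    def test_inclusion_5_properties_in_target_range(self):
        scene = make_phantom_scene(inclusion=5)
        assert 0.03 <= scene.zone_props.mua <= 0.036
        assert 2.75 <= scene.zone_props.musp <= 3.50

    def test_background_agar_at_750(self):
        scene = make_phantom_scene(inclusion=1)
        assert scene.background.mua == pytest.approx(0.006)
        assert scene.background.musp == pytest.approx(1.07)

    def test_zone_center_depth_is_gap_plus_radius(self):
        scene = make_phantom_scene(inclusion=1)
        assert scene.zone.center[2] == pytest.approx(2.7 + 10.0)
        assert scene.zone.a == pytest.approx(10.0)

    def test_unknown_inclusion_rejected(self):
        with pytest.raises(ValueError, match="inclusion"):
            make_phantom_scene(inclusion=7)

    def test_explicit_props_and_id_are_exclusive(self):
        with pytest.raises(ValueError):
            make_phantom_scene(inclusion=1, zone_props=NATIVE)

    def test_inclusion_truncated_to_domain(self):
        scene = make_phantom_scene(inclusion=1)
        assert 2 * scene.zone.b <= scene.grid.domain[1]


class TestCoagulationContrast:
    def test_default_contrast_doubles_scattering(self):
        coag = coagulated_from_native(NATIVE)
        assert coag.musp == pytest.approx(2.0 * NATIVE.musp)
        assert coag.mua == pytest.approx(0.6 * NATIVE.mua)


class TestGrowthProtocol:
    def test_default_rate_half_mm_per_scan(self):
        proto = GrowthProtocol()
        r0 = proto.radius_at(0.0)
        r1 = proto.radius_at(28.0)
        assert r1 - r0 == pytest.approx(0.5)

    def test_dual_power_increment_ratio(self):
        proto = GrowthProtocol(schedule=((0.0, 280.0, 3.0), (280.0, 560.0, 5.0)))
        inc_low = proto.radius_at(56.0) - proto.radius_at(28.0)
        inc_high = proto.radius_at(336.0) - proto.radius_at(308.0)
        assert inc_high / inc_low == pytest.approx(5.0 / 3.0)

    def test_radius_frozen_after_laser_off(self):
        proto = GrowthProtocol(schedule=((0.0, 280.0, 3.0),))
        assert proto.radius_at(400.0) == proto.radius_at(280.0)

    def test_non_contiguous_schedule_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            GrowthProtocol(schedule=((0.0, 100.0, 3.0), (150.0, 200.0, 5.0)))


@pytest.fixture(scope="module")
def quiet():
    return NoiseModel(sigma=0.0, fluct_amplitude=0.0)


class TestSimulateTreatment:

    def test_zero_noise_zero_rate_frames_identical(self, fast_grid, layout, quiet):
        proto = GrowthProtocol(schedule=((0.0, 84.0, 3.0),), rate_mm_per_scan=0.0,
                               initial_radius=5.0, fiber_depth=12.0)
        frames, _ = simulate_treatment(proto, NATIVE, None, quiet, layout,
                                       grid=fast_grid, n_post_scans=0)
        assert len(frames) == 3
        for f in frames[1:]:
            assert np.allclose(f.intensities, frames[0].intensities)

    def test_truth_nondecreasing_then_flat(self, fast_grid, layout, quiet):
        proto = GrowthProtocol(schedule=((0.0, 112.0, 3.0),), initial_radius=3.0,
                               fiber_depth=12.0)
        _, truth = simulate_treatment(proto, NATIVE, None, quiet, layout,
                                      grid=fast_grid, n_post_scans=3)
        r = truth.true_radius_mm.to_numpy()
        assert np.all(np.diff(r) >= -1e-12)
        post = truth.loc[~truth.lasing, "true_radius_mm"]
        assert post.max() - post.min() < 1e-12

    def test_truncates_at_probe_safety_margin(self, fast_grid, layout, quiet):
        proto = GrowthProtocol(schedule=((0.0, 744.0, 3.0),), initial_radius=5.0,
                               fiber_depth=8.0)
        frames, truth = simulate_treatment(proto, NATIVE, None, quiet, layout,
                                           grid=fast_grid)
        assert truth.attrs["truncated"]
        assert 8.0 - truth.true_radius_mm.max() > 0.4

    def test_four_source_mode_masks_rows(self, fast_grid, layout, quiet):
        proto = GrowthProtocol(schedule=((0.0, 28.0, 3.0),), initial_radius=5.0,
                               fiber_depth=12.0, scan_period=14.0)
        frames, _ = simulate_treatment(proto, NATIVE, None, quiet, layout,
                                       grid=fast_grid, n_post_scans=0,
                                       active_sources=[0, 2, 4, 6])
        assert frames[0].mask[0].all() and not frames[0].mask[1].any()
        assert frames[0].n_valid == 32

    def test_noise_cov_close_to_nominal(self, fast_grid, layout):
        """Per-channel CoV over repeated scans matches sigma = 1% within 20%."""
        proto = GrowthProtocol(schedule=((0.0, 28.0 * 100, 3.0),),
                               rate_mm_per_scan=0.0, initial_radius=5.0,
                               fiber_depth=12.0)
        frames, _ = simulate_treatment(proto, NATIVE, None,
                                       NoiseModel(sigma=0.01, fluct_amplitude=0.0,
                                                  seed=42),
                                       layout, grid=fast_grid, n_post_scans=0)
        stack = np.stack([f.intensities for f in frames])
        cov = stack.std(axis=0, ddof=1) / stack.mean(axis=0)
        assert 0.008 <= cov.mean() <= 0.012
        assert 0.006 <= cov.min() and cov.max() <= 0.014

    def test_physiological_modulation_is_cyclic(self):
        nm = NoiseModel(sigma=0.0, fluct_amplitude=0.1, fluct_period_s=60.0)
        assert nm.mua_modulation(15.0) == pytest.approx(1.1)
        assert nm.mua_modulation(45.0) == pytest.approx(0.9)
        assert nm.mua_modulation(60.0) == pytest.approx(1.0, abs=1e-12)

    def test_reproducible_given_seed(self, fast_grid, layout):
        proto = GrowthProtocol(schedule=((0.0, 56.0, 3.0),), initial_radius=5.0,
                               fiber_depth=12.0)
        nm = NoiseModel(sigma=0.01, fluct_amplitude=0.0, seed=5)
        f1, _ = simulate_treatment(proto, NATIVE, None, nm, layout,
                                   grid=fast_grid, n_post_scans=0)
        f2, _ = simulate_treatment(proto, NATIVE, None, nm, layout,
                                   grid=fast_grid, n_post_scans=0)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.intensities, b.intensities)


class TestTemperatureMap:
    def test_gaussian_isotherm_radius_closed_form(self):
        tmap = make_temperature_map(None, peak=90, baseline=37, sigma_mm=5.0,
                                    extent_mm=40)
        # build directly with sigma: T(r)=37+53 exp(-r^2/50); 55 deg C at
        tmap = make_temperature_map(7.0, peak=90, baseline=37, sigma_mm=5.0)
        expected = 5.0 * math.sqrt(2.0 * math.log(53.0 / 18.0))
        r, contour, flags = extract_isotherm_radius(tmap)
        assert not flags["sub_threshold"]
        assert r == pytest.approx(expected, abs=0.5)

    def test_requested_radius_round_trip(self):
        tmap = make_temperature_map(8.0, peak=90, baseline=37)
        r, _, flags = extract_isotherm_radius(tmap)
        assert r == pytest.approx(8.0, abs=0.5)

    def test_baseline_only_map_flagged(self):
        tmap = make_temperature_map(None, baseline=37.0)
        assert tmap.sub_threshold
        r, contour, flags = extract_isotherm_radius(tmap)
        assert r is None and flags["sub_threshold"]

    def test_sub_threshold_peak_flagged(self):
        tmap = make_temperature_map(5.0, peak=50.0, baseline=37.0)
        assert tmap.sub_threshold

    def test_uniform_hot_map_degenerate(self):
        tmap = make_temperature_map(None, baseline=60.0)
        r, contour, flags = extract_isotherm_radius(tmap)
        assert flags["degenerate"]

    def test_threshold_sweep_monotone(self):
        """With a realistic radial gradient the isotherm shrinks as the
        assumed coagulation temperature rises (53 -> 57 deg C)."""
        tmap = make_temperature_map(8.0, peak=90, baseline=37)
        radii = [extract_isotherm_radius(tmap, threshold=th)[0]
                 for th in (53, 54, 55, 56, 57)]
        assert all(r2 < r1 for r1, r2 in zip(radii, radii[1:]))
        assert radii[0] - radii[-1] < 1.5
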