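"""Particle-ensemble simulator: schedules, motion, rasterization, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xpcsre as xr
from xpcsre.errors import ParameterError, PlacementError
from xpcsre.particles import as_schedule


class TestSchedules:
    def test_midpoint_of_line(self):
        s = as_schedule([(0.0, 2.0), (100.0, 12.0)])
        assert xr.radius_at(s, 50.0) == pytest.approx(7.0)

    def test_clamps_outside_range(self):
        s = as_schedule([(0.0, 2.0), (100.0, 12.0)])
        assert xr.radius_at(s, -5.0) == 2.0
        assert xr.radius_at(s, 1e6) == 12.0

    def test_single_point_is_constant(self):
        s = as_schedule(3.5)
        assert xr.radius_at(s, 0.0) == xr.radius_at(s, 999.0) == 3.5

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ParameterError):
            as_schedule([(0.0, 1.0), (0.0, 2.0)])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        t=st.floats(min_value=-50, max_value=250),
        v0=st.floats(min_value=0, max_value=10),
        v1=st.floats(min_value=0, max_value=10),
    )
    def test_interpolation_bounded_by_control_values(self, t, v0, v1):
        s = as_schedule([(0.0, v0), (200.0, v1)])
        lo, hi = min(v0, v1), max(v0, v1)
        assert lo - 1e-9 <= xr.radius_at(s, t) <= hi + 1e-9


class TestSampling:
    def test_same_seed_identical_ensembles(self):
        spec = xr.ParticleEnsembleSpec(n_particles=20, box_n=64, seed=9)
        a = xr.sample_ensemble(spec, 10)
        b = xr.sample_ensemble(spec, 10)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.radii0, b.radii0)

    def test_zero_spread_degenerate_radii(self):
        spec = xr.ParticleEnsembleSpec(n_particles=15, box_n=64, radius_mean=3.0, radius_spread=0.0)
        ens = xr.sample_ensemble(spec, 1)
        assert np.all(ens.radii0 == 3.0)

    def test_uniform_placement_mean_near_box_centre(self):
        # direct Monte-Carlo check: mean of 10000 uniform draws on [0, L)
        # is L/2 within ~3 sigma = 3 * L/sqrt(12)/100
        spec = xr.ParticleEnsembleSpec(n_particles=10_000, box_n=128, seed=1)
        ens = xr.sample_ensemble(spec, 1)
        assert np.allclose(ens.positions[0].mean(axis=0), 64.0, atol=0.01 * 128)

    def test_min_separation_respected(self):
        spec = xr.ParticleEnsembleSpec(
            n_particles=40, box_n=128, min_separation=10.0, seed=2
        )
        ens = xr.sample_ensemble(spec, 1)
        p = ens.positions[0]
        d = p[:, None, :] - p[None, :, :]
        d -= 128 * np.round(d / 128)
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= 10.0

    def test_infeasible_packing_raises(self):
        spec = xr.ParticleEnsembleSpec(n_particles=200, box_n=32, min_separation=10.0)
        with pytest.raises(PlacementError):
            xr.sample_ensemble(spec, 1)


class TestMotion:
    def test_zero_sigma_positions_frozen(self):
        spec = xr.ParticleEnsembleSpec(
            n_particles=10, box_n=64, motion=xr.MotionSpec(kind="random_walk", step_sigma=0.0)
        )
        ens = xr.sample_ensemble(spec, 15)
        assert np.array_equal(ens.positions[0], ens.positions[-1])

    def test_positions_stay_in_box(self):
        spec = xr.ParticleEnsembleSpec(
            n_particles=50, box_n=64, seed=3,
            motion=xr.MotionSpec(kind="random_walk", step_sigma=20.0),
        )
        ens = xr.sample_ensemble(spec, 30)
        assert np.all(ens.positions >= 0) and np.all(ens.positions < 64)

    def test_msd_matches_closed_form(self):
        # 2D random walk: MSD(n steps) = 2 n sigma^2; track with minimal-image
        # unwrapping at small total displacement
        sigma, n_steps = 0.5, 100
        spec = xr.ParticleEnsembleSpec(
            n_particles=1000, box_n=256, seed=4,
            motion=xr.MotionSpec(kind="random_walk", step_sigma=sigma),
        )
        ens = xr.sample_ensemble(spec, n_steps + 1)
        steps = np.diff(ens.positions, axis=0)
        steps -= 256 * np.round(steps / 256)
        disp = steps.sum(axis=0)
        msd = (disp**2).sum(axis=1).mean()
        assert msd == pytest.approx(2 * n_steps * sigma**2, rel=0.05)

    def test_static_spec_with_nonzero_sigma_rejected(self):
        with pytest.raises(ParameterError):
            xr.MotionSpec(kind="static", step_sigma=1.0)


class TestRasterize:
    def test_empty_field_is_background(self):
        spec = xr.ParticleEnsembleSpec(n_particles=1, box_n=64, radius_mean=1e-6)
        ens = xr.sample_ensemble(spec, 1)
        ens.radii0[:] = 0.0
        f = xr.rasterize(ens, 0)
        assert np.all(f.values == spec.u_out_at(0.0))

    def test_disk_pixel_count_near_area(self):
        # one centred disk radius 20: pixel count within a perimeter of pi r^2
        spec = xr.ParticleEnsembleSpec(n_particles=1, box_n=256, radius_mean=20.0)
        ens = xr.sample_ensemble(spec, 1)
        ens.positions[0, 0] = [128.0, 128.0]
        f = xr.rasterize(ens, 0)
        count = int((f.values == -1.0).sum())
        assert abs(count - np.pi * 400) <= 2 * np.pi * 20

    def test_interior_count_matches_direct_oracle(self):
        # brute-force pixel-centre test against the vectorized painter
        spec = xr.ParticleEnsembleSpec(n_particles=1, box_n=64, radius_mean=7.3)
        ens = xr.sample_ensemble(spec, 1)
        cx, cy = ens.positions[0, 0]
        f = xr.rasterize(ens, 0)
        direct = np.zeros((64, 64), dtype=bool)
        for i in range(64):
            for j in range(64):
                dx = (i - cx + 32) % 64 - 32
                dy = (j - cy + 32) % 64 - 32
                direct[i, j] = dx**2 + dy**2 <= 7.3**2
        assert np.array_equal(f.values == -1.0, direct)

    def test_fully_overlapping_disks_union(self):
        spec = xr.ParticleEnsembleSpec(n_particles=2, box_n=64, radius_mean=8.0)
        ens = xr.sample_ensemble(spec, 1)
        ens.positions[0, 1] = ens.positions[0, 0]
        two = xr.rasterize(ens, 0)
        solo = xr.ParticleEnsembleSpec(n_particles=1, box_n=64, radius_mean=8.0)
        ens1 = xr.sample_ensemble(solo, 1)
        ens1.positions[0, 0] = ens.positions[0, 0]
        one = xr.rasterize(ens1, 0)
        assert np.array_equal(two.values, one.values)

    def test_periodic_wrapping_of_shapes(self):
        spec = xr.ParticleEnsembleSpec(n_particles=1, box_n=64, radius_mean=6.0)
        ens = xr.sample_ensemble(spec, 1)
        ens.positions[0, 0] = [0.0, 0.0]  # corner: disk wraps to all four corners
        f = xr.rasterize(ens, 0)
        assert f.values[0, 0] == -1.0 and f.values[-1, -1] == -1.0

    def test_ellipse_preserves_area(self):
        base = dict(n_particles=1, box_n=256, radius_mean=15.0)
        disk = xr.rasterize(xr.sample_ensemble(xr.ParticleEnsembleSpec(**base), 1), 0)
        squashed = xr.ParticleEnsembleSpec(
            **base, shape_schedule=xr.ShapeSchedule.constant(0.5)
        )
        ell = xr.rasterize(xr.sample_ensemble(squashed, 1), 0)
        a_disk = (disk.values == -1).sum()
        a_ell = (ell.values == -1).sum()
        assert abs(a_ell - a_disk) / a_disk < 0.03


class TestSimulate:
    def test_frozen_scenario_identical_frames(self, frozen_speckle):
        stack = frozen_speckle.stack()
        assert np.array_equal(stack[0], stack[-1])

    def test_end_to_end_determinism(self):
        spec = xr.build_scenario("brownian", box_n=64, n_particles=10, seed=6)
        a = xr.simulate(spec, 12).stack()
        b = xr.simulate(spec, 12).stack()
        assert np.array_equal(a, b)


class TestScenarios:
    def test_unknown_name_lists_presets(self):
        with pytest.raises(ParameterError, match="linear_growth"):
            xr.build_scenario("not_a_scenario")

    def test_overrides_change_only_named_fields(self):
        base = xr.build_scenario("linear_growth", seed=1)
        mod = xr.build_scenario("linear_growth", seed=1, overrides={"radius_mean": 9.0})
        assert mod.radius_mean == 9.0
        assert mod.n_particles == base.n_particles
        assert mod.radius_schedule == base.radius_schedule

    def test_unknown_override_rejected(self):
        with pytest.raises(ParameterError, match="bogus"):
            xr.build_scenario("linear_growth", overrides={"bogus": 1})

    def test_all_presets_buildable_and_simulable(self):
        for name in xr.SCENARIO_NAMES:
            spec = xr.build_scenario(name, box_n=32, n_particles=3, duration=5.0, seed=0)
            series = xr.simulate(spec, 3)
            assert len(series) == 3

    def test_two_step_small_particles_dissolve_first(self):
        spec = xr.build_scenario(
            "two_step_growth_dissolution", n_particles=50, box_n=128,
            duration=100.0, rate_ratio=1.0, seed=3,
        )
        ens = xr.sample_ensemble(spec, 100)
        late = ens.radii_at(90.0)
        order = np.argsort(ens.radii0)
        # the smallest initial particles start dissolving first, so by late
        # times they have lost more radius relative to their peak
        peak = ens.radii_at(30.0)
        loss = peak - late
        assert loss[order[:10]].mean() > loss[order[-10:]].mean()

    def test_two_step_infinite_ratio_freezes_sizes(self):
        spec = xr.build_scenario(
            "two_step_growth_dissolution", n_particles=20, box_n=64,
            duration=100.0, rate_ratio=float("inf"), seed=3,
        )
        ens = xr.sample_ensemble(spec, 100)
        assert np.allclose(ens.radii_at(40.0), ens.radii_at(99.0))
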