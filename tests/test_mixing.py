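"""Mixing simulation and the pixel-CV mixing-time statistic."""

import math

import numpy as np
import pytest

from dropxtal.mixing import (
    CvTrace,
    MixingSimConfig,
    crystal_passivity_check,
    extract_kymograph,
    mixing_time,
    mixing_time_stats,
    pixel_cv,
    run_mixing_sim,
)
from dropxtal.synthetic_data import ImagingConfig, gen_cv_trace, gen_mixing_frames

from conftest import diffusion_only_oracle


class TestPixelCv:
    def test_uniform_frame_is_zero(self):
        assert pixel_cv(np.full((16, 16), 7.0)) == 0.0

    def test_half_zero_half_two(self):
        frame = np.concatenate([np.zeros(8), np.full(8, 2.0)]).reshape(4, 4)
        assert pixel_cv(frame) == pytest.approx(1.0)

    def test_three_levels_population_sd(self):
        frame = np.array([[1.0, 2.0, 3.0]])
        assert pixel_cv(frame) == pytest.approx(0.4082, abs=1e-4)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            pixel_cv(np.zeros((4, 4)))

    def test_mask_selects_pixels(self):
        frame = np.array([[1.0, 100.0], [1.0, 1.0]])
        mask = np.array([[True, False], [True, True]])
        assert pixel_cv(frame, mask) == 0.0


class TestMixingTime:
    def test_starts_below_threshold(self):
        trace = CvTrace(np.arange(5.0), np.full(5, 0.04))
        assert mixing_time(trace) == 0.0

    def test_linear_interpolation(self):
        trace = CvTrace(np.array([0.0, 10.0]), np.array([1.0, 0.0]))
        assert mixing_time(trace) == pytest.approx(9.5)

    def test_never_crossing_returns_nan(self):
        trace = CvTrace(np.arange(5.0), np.linspace(1.0, 0.5, 5))
        assert math.isnan(mixing_time(trace))

    def test_exponential_fixture_crossing(self):
        trace, t_true = gen_cv_trace(1.0, 1.0, 0.05, 120, threshold=0.05)
        assert mixing_time(trace) == pytest.approx(t_true, abs=0.025)


class TestMixingTimeStats:
    def test_identical_traces_zero_sd(self):
        trace, _ = gen_cv_trace(1.0, 1.0, 0.05, 120)
        stats = mixing_time_stats([trace] * 15)
        assert stats.n == 15
        assert stats.sd == pytest.approx(0.0, abs=1e-12)

    def test_known_crossings(self):
        traces = [
            CvTrace(np.array([0.0, t]), np.array([1.0, 0.05]))
            for t in (1.0, 2.0, 3.0)
        ]
        stats = mixing_time_stats(traces)
        assert stats.mean == pytest.approx(2.0)
        assert stats.sd == pytest.approx(1.0)

    def test_seeded_noisy_fixtures_recover_crossing(self):
        traces = [
            gen_cv_trace(1.0, 1.0, 0.05, 120, noise_sd=0.005, seed=s)[0]
            for s in range(15)
        ]
        stats = mixing_time_stats(traces)
        assert stats.mean == pytest.approx(2.996, abs=0.1)

    def test_undefined_crossings_counted_separately(self):
        crossing, _ = gen_cv_trace(1.0, 1.0, 0.05, 120)
        flat = CvTrace(np.arange(5.0), np.full(5, 0.9))
        stats = mixing_time_stats([crossing, flat])
        assert stats.n == 1 and stats.n_undefined == 1

    def test_all_undefined_rejected(self):
        flat = CvTrace(np.arange(5.0), np.full(5, 0.9))
        with pytest.raises(ValueError):
            mixing_time_stats([flat])


class TestExtractKymograph:
    def test_constant_frames_constant_trace(self):
        frames = np.full((6, 16, 16), 50.0)
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 4:12] = True
        trace = extract_kymograph(frames, mask, 0.1)
        assert trace.times.size == 6
        assert (trace.cv == 0).all()

    def test_lost_track_truncates(self):
        frames = np.full((6, 8, 8), 50.0)
        masks = [np.ones((8, 8), dtype=bool)] * 3 + [np.zeros((8, 8), dtype=bool)]
        trace = extract_kymograph(frames, masks, 0.1)
        assert trace.truncated
        assert trace.times.size == 3

    def test_roundtrip_through_rendered_frames(self):
        cfg = MixingSimConfig(droplet_volume=39, velocity=300, grid_n=64,
                              t_max=2.0, n_outputs=40)
        sim = run_mixing_sim(cfg)
        dt = float(sim.times[1] - sim.times[0])
        imaging = ImagingConfig(noise_sd=0.0, seed=0)
        stack, truth = gen_mixing_frames(sim.fields, sim.fluid_mask, dt, imaging)
        measured = extract_kymograph(stack, sim.fluid_mask, dt,
                                     invert_from=truth.dye_free_level)
        # intensity quantization to 16-bit is the only error source
        assert measured.cv == pytest.approx(sim.trace.cv, abs=5e-3)


class TestSimulation:
    def test_diffusion_only_matches_independent_oracle(self):
        cfg = MixingSimConfig(droplet_volume=39, velocity=0.0, diffusivity=500.0,
                              dye_volume_fraction=0.5, init_mode="fusion",
                              grid_n=64, t_max=20.0, n_outputs=20,
                              store_fields=False)
        sim = run_mixing_sim(cfg)
        oracle = diffusion_only_oracle(cfg, sim.times[1:])
        assert sim.trace.cv[1:] == pytest.approx(oracle, rel=0.05)

    def test_long_time_homogenization(self, mixing_suite):
        assert mixing_suite["phi_0.5"].trace.cv[-1] < 1e-3

    def test_mass_conservation_all_configs(self, mixing_suite):
        for name, sim in mixing_suite.items():
            assert sim.mass_drift <= 1e-3, name

    def test_cv_nonincreasing_without_advection(self):
        cfg = MixingSimConfig(droplet_volume=39, velocity=0.0, diffusivity=500.0,
                              init_mode="fusion", grid_n=64, t_max=20.0,
                              n_outputs=50, store_fields=False)
        sim = run_mixing_sim(cfg)
        start = int(0.05 * sim.trace.cv.size)
        diffs = np.diff(sim.trace.cv[start:])
        assert (diffs <= 1e-3).all()

    def test_cv_approximately_nonincreasing_with_advection(self, mixing_suite):
        for name, sim in mixing_suite.items():
            cv = sim.trace.cv
            start = max(1, int(0.05 * cv.size))
            rises = np.diff(cv[start:])
            allowed = 0.05 * cv[start:-1]
            assert (rises <= allowed).all(), name

    def test_entropy_of_mixing_ordering(self, mixing_suite):
        t = {phi: mixing_suite[f"phi_{phi}"].mixing_time for phi in (0.1, 0.3, 0.5)}
        assert t[0.5] < t[0.3] < t[0.1]

    def test_velocity_monotonicity(self, mixing_suite):
        t60 = mixing_suite["u_60"].mixing_time
        t150 = mixing_suite["u_150"].mixing_time
        t300 = mixing_suite["phi_0.5"].mixing_time
        assert t300 < t150 < t60

    def test_fusion_slower_than_generation(self, mixing_suite):
        assert (
            mixing_suite["fus_100"].mixing_time
            > mixing_suite["gen_100"].mixing_time
        )

    def test_unstable_dt_rejected_before_run(self):
        with pytest.raises(ValueError, match="stability"):
            run_mixing_sim(
                MixingSimConfig(droplet_volume=39, velocity=300, grid_n=64,
                                t_max=1.0, dt=0.1)
            )

    def test_unresolved_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_n"):
            MixingSimConfig(droplet_volume=39, velocity=300, grid_n=32)

    def test_rerun_deterministic(self):
        cfg = MixingSimConfig(droplet_volume=39, velocity=300, grid_n=64,
                              t_max=1.0, n_outputs=20, store_fields=False)
        a = run_mixing_sim(cfg)
        b = run_mixing_sim(cfg)
        assert np.array_equal(a.trace.cv, b.trace.cv)


@pytest.fixture(scope="module")
def passivity():
    cfg = MixingSimConfig(droplet_volume=39, velocity=300, grid_n=64,
                          t_max=10.0, n_outputs=150, store_fields=False)
    return crystal_passivity_check(cfg, crystal_mask_fraction=0.01)


class TestCrystalPassivity:
    def test_zero_mask_identical(self):
        cfg = MixingSimConfig(droplet_volume=39, velocity=300, grid_n=64,
                              t_max=1.0, n_outputs=20, store_fields=False)
        res = crystal_passivity_check(cfg, crystal_mask_fraction=0.0)
        assert np.array_equal(res.with_crystal.trace.cv, res.without_crystal.trace.cv)

    def test_small_crystal_barely_changes_mixing(self, passivity):
        t_with, t_without = passivity.mixing_times
        assert abs(t_with - t_without) <= 0.10 * t_without

    def test_oversized_mask_rejected(self):
        cfg = MixingSimConfig(droplet_volume=39, velocity=300, grid_n=64, t_max=1.0)
        with pytest.raises(ValueError):
            crystal_passivity_check(cfg, crystal_mask_fraction=0.2)
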