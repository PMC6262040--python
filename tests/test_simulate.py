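"""Generator correctness: growth rules, rendering, signals, determinism."""

import numpy as np
import pytest

import hyphatrack as ht
from hyphatrack.simulate import ground_truth_tracks


class TestSimulateMycelium:
    def test_non_germinating_spore_yields_empty_geometry(self):
        params = ht.SimulationParams(seed=5, germination_prob=0.0)
        geometry, truth = ht.simulate_mycelium(params)
        assert not truth.germinated
        assert truth.germination_time_h is None
        assert all(len(frame) == 0 for frame in geometry)
        assert truth.total_length_um.max() == 0.0
        assert truth.tip_count.max() == 0

    def test_germination_delay_distribution_matches_parameters(self):
        """Sampled germination times average to the configured 10.0 h."""
        times = []
        for seed in range(50):
            params = ht.SimulationParams(seed=seed, n_frames=40,
                                         max_total_length_um=50.0)
            _, truth = ht.simulate_mycelium(params)
            times.append(truth.germination_time_h)
        times = np.asarray(times)
        sem = times.std(ddof=1) / np.sqrt(len(times))
        assert abs(times.mean() - 10.0) <= 2 * sem

    def test_total_length_is_non_decreasing(self):
        for seed in (0, 1, 2):
            params = ht.SimulationParams(seed=seed, n_frames=40)
            _, truth = ht.simulate_mycelium(params)
            assert np.all(np.diff(truth.total_length_um) >= -1e-9)

    def test_tip_count_zero_before_germination(self, fast_run):
        _, truth, _ = fast_run
        before = truth.times_h < truth.germination_time_h
        assert np.all(truth.tip_count[before] == 0)

    def test_hgu_branching_rule_bounds_the_quotient(self):
        """Length per tip never exceeds target + one frame of growth."""
        params = ht.SimulationParams(seed=2, n_frames=50, target_hgu_um=30.0,
                                     tip_rate_mean_um_h=15.0,
                                     tip_rate_sd_um_h=0.0)
        _, truth = ht.simulate_mycelium(params)
        grown = truth.tip_count > 0
        quotient = truth.total_length_um[grown] / truth.tip_count[grown]
        bound = 30.0 + 15.0 * params.frame_interval_h
        assert quotient.max() <= bound

    def test_branching_drives_exponential_growth_at_rate_v_over_hgu(self):
        """Asymptotic rate of total length ~ tip_rate / HGU (= 0.5/h)."""
        slopes = []
        for seed in range(20):
            params = ht.SimulationParams(
                seed=seed, n_frames=40, target_hgu_um=30.0,
                tip_rate_mean_um_h=15.0, tip_rate_sd_um_h=0.0,
                germ_delay_mean_h=2.0, germ_delay_sd_h=0.5,
                tip_avoidance=False)
            _, truth = ht.simulate_mycelium(params)
            # past the ramp-up, before the chamber-capacity cap
            sel = ((truth.total_length_um > 100.0)
                   & (truth.total_length_um < 2000.0))
            t = truth.times_h[sel]
            if len(t) < 5:
                continue
            slopes.append(np.polyfit(t, np.log(truth.total_length_um[sel]),
                                     1)[0])
        assert abs(np.mean(slopes) - 0.5) <= 0.2 * 0.5

    def test_seed_determinism(self):
        params = ht.SimulationParams(seed=7, n_frames=40)
        g1, t1 = ht.simulate_mycelium(params)
        g2, t2 = ht.simulate_mycelium(params)
        assert t1.germination_time_h == t2.germination_time_h
        assert np.array_equal(t1.total_length_um, t2.total_length_um)
        for f1, f2 in zip(g1, g2):
            assert len(f1) == len(f2)
            for p1, p2 in zip(f1, f2):
                assert np.array_equal(p1, p2)

    def test_branch_tip_rate_closure_without_obstruction(self):
        """Measured arc growth equals the recorded per-tip rate."""
        checked = 0
        for seed in range(5):
            params = ht.SimulationParams(seed=seed, n_frames=24,
                                         germ_delay_mean_h=2.0,
                                         germ_delay_sd_h=0.2,
                                         tip_rate_sd_um_h=2.0,
                                         angle_noise_rad=0.0,
                                         tip_avoidance=False)
            geometry, truth = ht.simulate_mycelium(params)
            tracks = ground_truth_tracks(geometry, params.timestamps_h)
            for track in tracks:
                record = truth.tips[track.track_id]
                if record.is_primary or len(track.samples) < 3:
                    continue
                # closure holds only for tips that never hit a wall —
                # check the full polyline, not just the frame samples
                poly = geometry[-1][track.track_id]
                wall = min(poly[:, 0].min(), 90 - poly[:, 0].max(),
                           poly[:, 1].min(), 40 - poly[:, 1].max())
                if wall < 0.5:
                    continue
                rate = ((track.final_length_um - track.initial_length_um)
                        / (track.times_h[-1] - track.times_h[0]))
                assert rate == pytest.approx(record.rate_um_h, rel=1e-6)
                checked += 1
        assert checked >= 3

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ht.SimulationParams(germination_prob=1.5).validate()
        with pytest.raises(ValueError):
            ht.SimulationParams(tip_rate_mean_um_h=-1.0).validate()
        with pytest.raises(ValueError):
            # horizon must cover the germination delay distribution
            ht.SimulationParams(n_frames=5).validate()


class TestRenderFrames:
    def test_empty_geometry_renders_background_noise(self):
        params = ht.SimulationParams(seed=1, germination_prob=0.0,
                                     n_frames=3)
        geometry, _ = ht.simulate_mycelium(params)
        stack = ht.render_frames(geometry, params)
        assert not stack.clean_masks.any()
        assert stack.frames.std() > 0  # noise present

    def test_single_hypha_mask_area_matches_rectangle(self):
        """10 um x 0.7 um hypha covers ~ analytic rasterized area."""
        params = ht.SimulationParams(seed=0, n_frames=1,
                                     germination_prob=0.0)
        geometry = [[np.array([[20.0, 20.0], [30.0, 20.0]])]]
        stack = ht.render_frames(geometry, params)
        area_px = stack.clean_masks[0].sum()
        # 100 px-long centreline stamped with a radius-3 disk
        expected = 100 * 7 + 2 * 12  # body + rounded end caps
        assert abs(area_px - expected) <= 0.15 * expected

    def test_noise_free_render_thresholds_to_clean_mask(self, fast_params):
        import dataclasses
        params = dataclasses.replace(fast_params, noise_sd=0.0)
        geometry, _ = ht.simulate_mycelium(params)
        stack = ht.render_frames(geometry, params, blur_sigma_px=0.0)
        mid = (200.0 + 60.0) / 2
        np.testing.assert_array_equal(stack.frames[-1] < mid,
                                      stack.clean_masks[-1])

    def test_coarse_pixels_raise_quality_flag(self):
        params = ht.SimulationParams(seed=1, pixel_size_um=1.0,
                                     germination_prob=0.0, n_frames=2)
        geometry, _ = ht.simulate_mycelium(params)
        stack = ht.render_frames(geometry, params)
        assert any("pixel_size" in flag for flag in stack.qc_flags)

    def test_masks_are_monotone_over_time(self, fast_run):
        _, _, stack = fast_run
        for k in range(1, stack.n_frames):
            grown_back = stack.clean_masks[k - 1] & ~stack.clean_masks[k]
            assert not grown_back.any()


class TestLengthCurve:
    def test_deterministic_exponential_values(self):
        times = np.arange(5.0)
        curve = ht.simulate_length_curve(np.log(2.0), 1.0, 0.0, times)
        np.testing.assert_allclose(curve, [1, 2, 4, 8, 16], rtol=1e-12)

    def test_empty_times_rejected(self):
        with pytest.raises(ValueError):
            ht.simulate_length_curve(0.3, 1.0, 0.0, np.array([]))


class TestScatterSignal:
    def test_pre_lag_is_constant_blank(self):
        params = ht.ScatterSignalParams(lag_h=10.0, noise_sd=0.0)
        sig = ht.simulate_scatter_signal(params)
        pre = sig.timestamps_h < 10.0
        np.testing.assert_allclose(sig.intensity[pre], 100.0)

    def test_log_slope_equals_mu_far_from_saturation(self):
        params = ht.ScatterSignalParams(lag_h=5.0, mu_h=0.3, noise_sd=0.0,
                                        saturation_level=1e6)
        sig = ht.simulate_scatter_signal(params)
        sel = (sig.timestamps_h > 5.0) & (sig.timestamps_h < 15.0)
        log_b = np.log(sig.intensity[sel] - 100.0)
        slope = np.polyfit(sig.timestamps_h[sel], log_b, 1)[0]
        assert slope == pytest.approx(0.3, rel=0.005)

    def test_signal_saturates_at_configured_level(self):
        params = ht.ScatterSignalParams(lag_h=2.0, mu_h=0.5, noise_sd=0.0,
                                        duration_h=60.0)
        sig = ht.simulate_scatter_signal(params)
        assert sig.intensity[-1] == pytest.approx(600.0, rel=0.02)
        assert sig.intensity.max() <= 600.0 + 1e-9
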