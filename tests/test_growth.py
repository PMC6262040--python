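"""Germination delay, gated log-linear growth fit, HGU, tip rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hyphatrack as ht
from hyphatrack.growth import MyceliumTimeSeries

from conftest import make_track


def series_of(lengths, tips=None, dt=1.0):
    lengths = np.asarray(lengths, dtype=float)
    tips = (np.ones_like(lengths, dtype=int) if tips is None
            else np.asarray(tips, dtype=int))
    return MyceliumTimeSeries(
        timestamps_h=np.arange(len(lengths)) * dt,
        total_length_um=lengths, tip_count=tips,
        coverage_fraction=np.zeros(len(lengths)))


class TestAssembleSeries:
    def test_totals_come_from_graphs(self):
        graphs = [ht.build_skeleton_graph(np.zeros((5, 5), bool), k * 0.5, 0.1,
                                          frame_index=k) for k in range(3)]
        series = ht.assemble_series(graphs, np.array([0.0, 0.1, 0.2]), 2)
        assert list(series.total_length_um) == [0.0, 0.0, 0.0]
        assert len(series) == 3

    def test_truncates_at_stop_index(self, fast_analysis):
        graphs = fast_analysis.graphs
        coverages = np.linspace(0, 0.1, len(graphs))
        series = ht.assemble_series(graphs, coverages, 2)
        assert len(series) == 3

    def test_empty_graphs_rejected(self):
        with pytest.raises(ValueError):
            ht.assemble_series([], np.array([]), 0)

    def test_matches_ground_truth_series(self, fast_run, fast_analysis):
        _, truth, _ = fast_run
        series = fast_analysis.series
        for k in range(len(series)):
            if truth.total_length_um[k] > 100.0:
                assert series.total_length_um[k] == pytest.approx(
                    truth.total_length_um[k], rel=0.08)


class TestGerminationDelay:
    def test_single_track_born_at_time_zero(self):
        track = make_track(np.arange(5) * 0.5, [1, 5, 9, 13, 17])
        assert ht.germination_delay([track]) == 0.0

    def test_minimum_birth_time_over_tracks(self):
        dt = 0.5
        tracks = [make_track(np.arange(f, f + 6) * dt, np.arange(6) * 4.0)
                  for f in (12, 7, 20)]
        assert ht.germination_delay(tracks) == pytest.approx(3.5)

    def test_no_tracks_means_non_germinated(self):
        assert ht.germination_delay([]) is None


class TestFitGrowthRate:
    def test_exact_geometric_series(self):
        fit = ht.fit_growth_rate(series_of([1, 2, 4, 8, 16]))
        assert fit.mu_h == pytest.approx(np.log(2.0), abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.window == (0, 4)
        assert fit.n_points == 5

    def test_constant_series_fails_gate(self):
        assert ht.fit_growth_rate(series_of([5, 5, 5, 5, 5])) is None

    def test_all_zero_series_gives_none(self):
        assert ht.fit_growth_rate(series_of([0, 0, 0, 0, 0, 0])) is None

    def test_noiseless_exponential_recovered_to_machine_precision(self):
        t = np.arange(30) * 0.5
        series = series_of(3.0 * np.exp(0.41 * t), dt=0.5)
        fit = ht.fit_growth_rate(series)
        assert fit.mu_h == pytest.approx(0.41, rel=1e-10)

    def test_window_skips_leading_zeros(self):
        lengths = [0, 0, 0] + list(2.0 ** np.arange(6))
        fit = ht.fit_growth_rate(series_of(lengths))
        assert fit.window[0] >= 3
        assert fit.mu_h == pytest.approx(np.log(2.0), rel=1e-9)

    def test_extending_series_never_worsens_reported_window(self):
        t = np.arange(20) * 0.5
        rng = np.random.default_rng(0)
        curve = 5.0 * np.exp(0.3 * t) * np.exp(rng.normal(0, 0.03, 20))
        short = ht.fit_growth_rate(series_of(curve[:12], dt=0.5))
        full = ht.fit_growth_rate(series_of(curve, dt=0.5))
        assert full.r_squared >= short.r_squared - 1e-12 or \
            full.n_points >= short.n_points


class TestHyphalGrowthUnit:
    def test_constant_quotient_is_invariant_under_smoothing(self):
        tips = np.array([1, 1, 2, 2, 4, 4, 8, 8])
        series = series_of(30.0 * tips, tips=tips)
        fit = ht.fit_growth_rate(series)
        assert ht.hyphal_growth_unit(series, fit) == pytest.approx(30.0)

    def test_hand_computed_max_without_smoothing(self):
        series = series_of([10, 20, 40], tips=[1, 1, 2])
        fit = ht.GrowthFit(mu_h=0.7, log_intercept=0.0, r_squared=1.0,
                           window=(0, 2), n_points=3)
        hgu = ht.hyphal_growth_unit(series, fit, smooth_window=1)
        assert hgu == pytest.approx(20.0)

    def test_absent_fit_gives_none(self):
        assert ht.hyphal_growth_unit(series_of([1, 2, 4]), None) is None

    def test_zero_tips_throughout_window_gives_none(self):
        series = series_of([1, 2, 4, 8, 16], tips=[0, 0, 0, 0, 0])
        fit = ht.GrowthFit(mu_h=0.7, log_intercept=0.0, r_squared=1.0,
                           window=(0, 4), n_points=5)
        assert ht.hyphal_growth_unit(series, fit) is None

    @given(scale=st.floats(0.1, 50.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_scaling_both_series(self, scale):
        tips = np.array([1, 1, 2, 3, 4, 6, 8, 11])
        lengths = 25.0 * tips + np.arange(8.0)
        series = series_of(lengths, tips=tips)
        scaled = series_of(lengths * scale,
                           tips=np.round(tips * 7).astype(int))
        fit = ht.GrowthFit(mu_h=0.5, log_intercept=0.0, r_squared=1.0,
                           window=(0, 7), n_points=8)
        base = ht.hyphal_growth_unit(series, fit)
        # multiplying length by c multiplies HGU by c (tips held fixed)
        assert ht.hyphal_growth_unit(series_of(lengths * scale, tips=tips),
                                     fit) == pytest.approx(base * scale)

    def test_invariant_to_uniform_time_rescaling(self):
        tips = np.array([1, 2, 2, 4, 5, 8])
        lengths = 20.0 * tips + 3.0
        fit = ht.GrowthFit(mu_h=0.5, log_intercept=0.0, r_squared=1.0,
                           window=(0, 5), n_points=6)
        h1 = ht.hyphal_growth_unit(series_of(lengths, tips=tips, dt=0.5), fit)
        h2 = ht.hyphal_growth_unit(series_of(lengths, tips=tips, dt=2.0), fit)
        assert h1 == pytest.approx(h2)


class TestTipElongationRates:
    def test_endpoint_difference_rate(self):
        track = make_track(np.arange(8) * 0.5, np.linspace(2, 20, 8))
        stats = ht.tip_elongation_rates([track])
        assert stats.per_track_rates_um_h[0] == pytest.approx(18 / 3.5)
        assert stats.n_tracks == 1

    def test_pooled_mean_and_sd(self):
        tracks = [make_track(np.arange(6) * 0.5, np.arange(6) * r, i)
                  for i, r in enumerate([2.0, 4.0, 6.0])]
        stats = ht.tip_elongation_rates(tracks)
        assert stats.mean_um_h == pytest.approx(8.0)   # rates 4, 8, 12
        assert stats.sd_um_h == pytest.approx(4.0)

    def test_single_sample_tracks_are_ignored(self):
        lonely = make_track([0.0], [1.0])
        stats = ht.tip_elongation_rates([lonely])
        assert stats.n_tracks == 0
        assert np.isnan(stats.mean_um_h)

    def test_instantaneous_rates_are_collected(self):
        track = make_track(np.arange(4) * 0.5, [0, 1, 3, 6])
        stats = ht.tip_elongation_rates([track])
        np.testing.assert_allclose(stats.instantaneous_rates_um_h,
                                   [2.0, 4.0, 6.0])
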