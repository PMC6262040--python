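"""Parameter-recovery studies: simulate at known ground truth, re-measure.

Every public function here runs one closed loop — generate synthetic data
with the generator, push it through the analysis pipeline, and return the
recovered per-replicate estimates — so that recovery of germination
delay, specific growth rate, HGU, tip elongation rate, lag phase and
germination fraction can be quantified against the generating values.
These drivers are shared by the validation test-suite and the
reproduction script.

Problem sizes default to the study sizes (50 chambers for delays, 30
geometric simulations for HGU, hundreds of chambers for the germination
fraction); rendering is clean-mask based and stops just above the 20 %
tracking cutoff, and germination-only runs cap mycelium growth at 300 um
since the first trackable hypha appears far below that.
"""

from __future__ import annotations

import numpy as np

from .growth import fit_growth_rate, germination_delay, tip_elongation_rates
from .growth import MyceliumTimeSeries
from .mtpc import blank_signal, lag_phase, mtpc_growth_rate
from .pipeline import analyze_chamber
from .simulate import (ScatterSignalParams, SimulationParams,
                       ground_truth_tracks, render_frames,
                       simulate_length_curve, simulate_mycelium,
                       simulate_scatter_signal)
from .tracking import filter_tracks


def _chamber_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def recover_growth_rate_mscc(mu_h: float = 0.38, n_series: int = 50,
                             seed: int = 0, noise_cv: float = 0.05,
                             l0_um: float = 30.0,
                             duration_h: float = 10.0,
                             interval_h: float = 0.5) -> np.ndarray:
    """Fit mu on noisy exponential total-length curves; one value each."""
    times = np.arange(0.0, duration_h + 1e-9, interval_h)
    out = []
    for s in _chamber_seeds(seed, n_series):
        curve = simulate_length_curve(mu_h, l0_um, noise_cv, times, seed=int(s))
        series = MyceliumTimeSeries(
            timestamps_h=times, total_length_um=curve,
            tip_count=np.ones_like(times, dtype=int),
            coverage_fraction=np.zeros_like(times))
        fit = fit_growth_rate(series)
        if fit is not None:
            out.append(fit.mu_h)
    return np.asarray(out)


def recover_mtpc_growth_rate(mu_h: float = 0.23, n_wells: int = 20,
                             seed: int = 0, lag_h: float = 9.3,
                             duration_h: float = 50.0) -> np.ndarray:
    """Spline S'/S growth-rate estimates on synthetic plate signals."""
    out = []
    for s in _chamber_seeds(seed, n_wells):
        sig = simulate_scatter_signal(ScatterSignalParams(
            lag_h=lag_h, mu_h=mu_h, duration_h=duration_h, seed=int(s)))
        blanked, _ = blank_signal(sig)
        mu, _flags = mtpc_growth_rate(blanked)
        out.append(mu)
    return np.asarray(out)


def recover_lag_phase(lag_h: float = 9.3, mu_h: float = 0.33,
                      n_wells: int = 10, seed: int = 0) -> np.ndarray:
    """Lag-phase estimates on synthetic plate signals."""
    out = []
    for s in _chamber_seeds(seed, n_wells):
        sig = simulate_scatter_signal(ScatterSignalParams(
            lag_h=lag_h, mu_h=mu_h, seed=int(s),
            duration_h=max(40.0, lag_h + 20.0)))
        blanked, _ = blank_signal(sig)
        lag = lag_phase(blanked)
        if lag is not None:
            out.append(lag)
    return np.asarray(out)


def recover_germination_delay(delay_mean_h: float, delay_sd_h: float,
                              n_chambers: int = 50, seed: int = 0,
                              n_frames: int | None = None) -> np.ndarray:
    """Image-pipeline germination delays over simulated chambers.

    Chambers whose spore produced no trackable hypha within the horizon
    are excluded (counted non-germinated), as in the chamber statistics.
    """
    if n_frames is None:
        # horizon: delay + 3 SD + 6 h for the first track to qualify
        n_frames = int(np.ceil((delay_mean_h + 3 * delay_sd_h + 6.0) / 0.5))
    out = []
    for s in _chamber_seeds(seed, n_chambers):
        params = SimulationParams(
            seed=int(s), n_frames=n_frames,
            germ_delay_mean_h=delay_mean_h, germ_delay_sd_h=delay_sd_h,
            max_total_length_um=300.0)
        geometry, _truth = simulate_mycelium(params)
        stack = render_frames(geometry, params, clean_only=True,
                              max_coverage=0.06)
        analysis = analyze_chamber(stack, use_clean_masks=True)
        if analysis.result.germination_time_h is not None:
            out.append(analysis.result.germination_time_h)
    return np.asarray(out)


def recover_hgu(target_hgu_um: float, tip_rate_mean_um_h: float,
                tip_rate_sd_um_h: float, n_sims: int = 30, seed: int = 0,
                n_frames: int = 110) -> np.ndarray:
    """Pipeline HGU estimates over geometric simulations.

    Only chambers holding a developed (>= 10 tips) mycelium contribute;
    sparse chambers carry a QC flag and are excluded — the automated
    analogue of curating properly grown positions.
    """
    out = []
    for s in _chamber_seeds(seed, n_sims):
        params = SimulationParams(
            seed=int(s), n_frames=n_frames,
            target_hgu_um=target_hgu_um,
            tip_rate_mean_um_h=tip_rate_mean_um_h,
            tip_rate_sd_um_h=tip_rate_sd_um_h)
        geometry, _truth = simulate_mycelium(params)
        stack = render_frames(geometry, params, clean_only=True,
                              max_coverage=0.25)
        # clean rasters have no threshold-boundary noise: spur pruning
        # off, so emerging branches are counted as early as possible
        analysis = analyze_chamber(stack, use_clean_masks=True,
                                   prune_spur_um=0.0, track=False)
        result = analysis.result
        if result.hgu_um is None:
            continue
        if any(f.startswith("underdeveloped") for f in result.qc_flags):
            continue
        out.append(result.hgu_um)
    return np.asarray(out)


def recover_tip_rates(rate_mean_um_h: float = 14.1,
                      rate_sd_um_h: float = 6.1,
                      n_chambers: int = 60, seed: int = 0) -> np.ndarray:
    """Per-track mean elongation rates of simulated branch tips.

    Tracks come straight from the generator's polylines (true arc
    lengths, unobstructed growth mode) and pass the standard track
    filters before pooling, isolating the rate statistic from
    segmentation effects.
    """
    rates: list[float] = []
    for s in _chamber_seeds(seed, n_chambers):
        params = SimulationParams(
            seed=int(s), n_frames=20,
            germ_delay_mean_h=2.0, germ_delay_sd_h=0.5,
            tip_rate_mean_um_h=rate_mean_um_h,
            tip_rate_sd_um_h=rate_sd_um_h,
            tip_avoidance=False)
        geometry, truth = simulate_mycelium(params)
        tracks = ground_truth_tracks(geometry, params.timestamps_h)
        branch = [t for t in tracks
                  if not truth.tips[t.track_id].is_primary]
        kept = filter_tracks(branch)
        stats = tip_elongation_rates(kept)
        rates.extend(stats.per_track_rates_um_h.tolist())
    return np.asarray(rates)


def recover_germination_fraction(probability: float = 0.3612,
                                 n_chambers: int = 400, seed: int = 0,
                                 delay_mean_h: float = 10.0,
                                 delay_sd_h: float = 2.4) -> float:
    """Fraction of simulated chambers called germinated by the pipeline."""
    n_frames = int(np.ceil((delay_mean_h + 3 * delay_sd_h + 6.0) / 0.5))
    calls = []
    for s in _chamber_seeds(seed, n_chambers):
        params = SimulationParams(
            seed=int(s), n_frames=n_frames,
            germination_prob=probability,
            germ_delay_mean_h=delay_mean_h, germ_delay_sd_h=delay_sd_h,
            max_total_length_um=300.0)
        geometry, _truth = simulate_mycelium(params)
        stack = render_frames(geometry, params, clean_only=True,
                              max_coverage=0.06)
        analysis = analyze_chamber(stack, use_clean_masks=True)
        calls.append(analysis.result.germination_time_h is not None)
    return float(np.mean(calls))
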