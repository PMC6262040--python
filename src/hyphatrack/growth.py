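"""Per-chamber growth readouts.

From the tracked skeleton sequence of one chamber this module computes the
four headline quantities of filamentous single-mycelium analysis:

* **germination delay** — birth time of the first trackable (filtered)
  hypha;
* **specific growth rate** mu (1/h) — slope of a log-linear (OLS) fit of
  total mycelium length over the longest contiguous window that passes an
  R^2 > 0.9 gate, i.e. the operational "exponential growth phase";
* **hyphal growth unit (HGU)** — maximum over that window of smoothed
  total length divided by smoothed tip count (um of hypha per growing
  tip);
* **tip elongation rates** — per-track mean rates (endpoint difference
  over elapsed time, robust to per-frame skeleton jitter) pooled into a
  mean +/- SD, with the frame-to-frame instantaneous rates retained for
  distribution views.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skelgraph import SkeletonGraph
from .tracking import HyphaTrack


@dataclass
class MyceliumTimeSeries:
    timestamps_h: np.ndarray
    total_length_um: np.ndarray
    tip_count: np.ndarray
    coverage_fraction: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.timestamps_h)
        if not (len(self.total_length_um) == len(self.tip_count)
                == len(self.coverage_fraction) == n):
            raise ValueError("all series must be aligned")
        if np.any(np.asarray(self.total_length_um) < 0):
            raise ValueError("total length must be non-negative")

    def __len__(self) -> int:
        return len(self.timestamps_h)


@dataclass
class GrowthFit:
    mu_h: float
    log_intercept: float
    r_squared: float
    window: tuple[int, int]       # inclusive frame-index range [start, end]
    n_points: int


@dataclass
class TipRateStats:
    per_track_rates_um_h: np.ndarray
    mean_um_h: float
    sd_um_h: float
    instantaneous_rates_um_h: np.ndarray
    n_tracks: int


@dataclass
class ChamberResult:
    chamber_id: str
    condition: str = ""
    germination_time_h: float | None = None
    growth_fit: GrowthFit | None = None
    hgu_um: float | None = None
    tip_rate_mean_um_h: float = float("nan")
    tip_rate_sd_um_h: float = float("nan")
    n_filtered_tracks: int = 0
    qc_flags: list[str] = field(default_factory=list)

    @property
    def germinated(self) -> bool:
        return self.germination_time_h is not None


def assemble_series(graphs: list[SkeletonGraph], coverages: np.ndarray,
                    stop_index: int) -> MyceliumTimeSeries:
    """Align per-frame totals and truncate at the coverage stop index."""
    if not graphs:
        raise ValueError("no skeleton graphs supplied")
    stop = min(stop_index, len(graphs) - 1)
    graphs = graphs[: stop + 1]
    return MyceliumTimeSeries(
        timestamps_h=np.array([g.timestamp_h for g in graphs]),
        total_length_um=np.array([g.total_length_um for g in graphs]),
        tip_count=np.array([g.tip_count for g in graphs], dtype=int),
        coverage_fraction=np.asarray(coverages[: stop + 1], dtype=float),
    )


def germination_delay(filtered_tracks: list[HyphaTrack]) -> float | None:
    """Birth time of the first trackable hypha; None = non-germinated."""
    if not filtered_tracks:
        return None
    return float(min(t.birth_time_h for t in filtered_tracks))


def fit_growth_rate(series: MyceliumTimeSeries, r2_gate: float = 0.9,
                    min_fit_points: int = 5) -> GrowthFit | None:
    """Gated log-linear regression of total length over time.

    Searches every contiguous window of >= ``min_fit_points`` frames with
    strictly positive length, keeps those with R^2 above the gate and
    returns the OLS fit on the longest one (earliest on ties).  Returns
    None when no window qualifies (including all-zero and constant
    series).
    """
    y_raw = np.asarray(series.total_length_um, dtype=float)
    t_raw = np.asarray(series.timestamps_h, dtype=float)
    pos = y_raw > 0
    if pos.sum() < min_fit_points:
        return None

    best: tuple[int, int] | None = None  # (length, -start) maximization
    best_fit: GrowthFit | None = None
    # iterate over contiguous runs of positive length
    run_starts = np.flatnonzero(pos & ~np.roll(pos, 1))
    if pos[0]:
        run_starts = np.unique(np.concatenate([[0], run_starts]))
    for rs in run_starts:
        re = rs
        while re + 1 < len(pos) and pos[re + 1]:
            re += 1
        t = t_raw[rs:re + 1]
        ly = np.log(y_raw[rs:re + 1])
        n = len(t)
        if n < min_fit_points:
            continue
        # prefix sums for O(1) OLS per window
        c1 = np.concatenate([[0.0], np.cumsum(t)])
        c2 = np.concatenate([[0.0], np.cumsum(t * t)])
        cy = np.concatenate([[0.0], np.cumsum(ly)])
        cyy = np.concatenate([[0.0], np.cumsum(ly * ly)])
        cty = np.concatenate([[0.0], np.cumsum(t * ly)])
        for s in range(0, n - min_fit_points + 1):
            for e in range(s + min_fit_points - 1, n):
                m = e - s + 1
                st = c1[e + 1] - c1[s]
                stt = c2[e + 1] - c2[s]
                sy = cy[e + 1] - cy[s]
                syy = cyy[e + 1] - cyy[s]
                sty = cty[e + 1] - cty[s]
                sxx = stt - st * st / m
                sxy = sty - st * sy / m
                syy_c = syy - sy * sy / m
                if sxx <= 0 or syy_c <= 0:
                    continue  # degenerate (constant) window
                slope = sxy / sxx
                r2 = (sxy * sxy) / (sxx * syy_c)
                if r2 > r2_gate:
                    key = (m, -(rs + s))
                    if best is None or key > best:
                        best = key
                        best_fit = GrowthFit(
                            mu_h=float(slope),
                            log_intercept=float((sy - slope * st) / m),
                            r_squared=float(r2),
                            window=(rs + s, rs + e),
                            n_points=m,
                        )
    return best_fit


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking edges."""
    return (
        pd.Series(np.asarray(values, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def hyphal_growth_unit(series: MyceliumTimeSeries, fit: GrowthFit | None,
                       smooth_window: int = 5) -> float | None:
    """Max of smoothed length / smoothed tip count over the fit window."""
    if fit is None:
        return None
    s, e = fit.window
    length_s = _smooth(series.total_length_um, smooth_window)[s:e + 1]
    tips_s = _smooth(series.tip_count, smooth_window)[s:e + 1]
    ok = tips_s > 0
    if not ok.any():
        return None
    return float(np.max(length_s[ok] / tips_s[ok]))


def tip_elongation_rates(filtered_tracks: list[HyphaTrack]) -> TipRateStats:
    """Per-track mean rates (endpoint difference / elapsed time), pooled."""
    rates = []
    inst = []
    for track in filtered_tracks:
        if len(track.samples) < 2:
            continue
        elapsed = track.times_h[-1] - track.times_h[0]
        rates.append((track.final_length_um - track.initial_length_um) / elapsed)
        inst.append(track.instantaneous_rates())
    rates = np.asarray(rates, dtype=float)
    return TipRateStats(
        per_track_rates_um_h=rates,
        mean_um_h=float(rates.mean()) if rates.size else float("nan"),
        sd_um_h=float(rates.std(ddof=1)) if rates.size > 1 else float("nan"),
        instantaneous_rates_um_h=(np.concatenate(inst) if inst
                                  else np.empty(0)),
        n_tracks=int(rates.size),
    )
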