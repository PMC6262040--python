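"""Run-level persistence: HDF5 bundle, CSV tables and figures.

One analysis run (many chambers, many wells, condition summaries and
pairwise tests) is written to a single HDF5 file with ``/chambers``,
``/wells`` and ``/conditions`` groups, mirrored by flat CSV tables, plus
optional matplotlib figures (per-chamber growth curves, per-condition box
plots, tip-rate histograms).  Exports are deterministic given identical
inputs, and `load_run` restores the condition summaries bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .growth import ChamberResult, MyceliumTimeSeries
from .mtpc import WellResult
from .stats import ConditionSummary, TTestResult

_NAN = float("nan")


@dataclass
class RunBundle:
    """Everything produced by one analysis run."""

    chambers: list[ChamberResult] = field(default_factory=list)
    series: dict[str, MyceliumTimeSeries] = field(default_factory=dict)
    wells: list[WellResult] = field(default_factory=list)
    summaries: list[ConditionSummary] = field(default_factory=list)
    ttests: list[TTestResult] = field(default_factory=list)


def chambers_table(chambers: list[ChamberResult]) -> pd.DataFrame:
    rows = []
    for c in chambers:
        fit = c.growth_fit
        rows.append({
            "chamber_id": c.chamber_id,
            "condition": c.condition,
            "germinated": c.germinated,
            "germination_time_h": (_NAN if c.germination_time_h is None
                                   else c.germination_time_h),
            "mu_h": _NAN if fit is None else fit.mu_h,
            "r_squared": _NAN if fit is None else fit.r_squared,
            "hgu_um": _NAN if c.hgu_um is None else c.hgu_um,
            "tip_rate_mean_um_h": c.tip_rate_mean_um_h,
            "tip_rate_sd_um_h": c.tip_rate_sd_um_h,
            "n_filtered_tracks": c.n_filtered_tracks,
            "qc_flags": ";".join(c.qc_flags),
        })
    return pd.DataFrame(rows)


def wells_table(wells: list[WellResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "well_id": w.well_id,
        "condition": w.condition,
        "blank_value": w.blank_value,
        "lag_phase_h": _NAN if w.lag_phase_h is None else w.lag_phase_h,
        "mu_h": _NAN if w.mu_h is None else w.mu_h,
        "qc_flags": ";".join(w.qc_flags),
    } for w in wells])


def summaries_table(summaries: list[ConditionSummary]) -> pd.DataFrame:
    return pd.DataFrame([{
        "medium_id": s.medium_id, "metric": s.metric,
        "n": s.n, "mean": s.mean, "sd": s.sd,
    } for s in summaries])


def ttests_table(ttests: list[TTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "metric": t.metric, "condition_a": t.condition_a,
        "condition_b": t.condition_b,
        "student_t": t.student_t, "student_df": t.student_df,
        "student_p": t.student_p,
        "welch_t": t.welch_t, "welch_df": t.welch_df, "welch_p": t.welch_p,
        "significant": t.significant,
    } for t in ttests])


def export_run(bundle: RunBundle, out_dir: str | Path,
               figures: bool = False) -> Path:
    """Write the HDF5 bundle + CSVs (+ figures) for one run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    h5_path = out_dir / "run.h5"
    with h5py.File(h5_path, "w") as f:
        g_ch = f.create_group("chambers")
        for c in bundle.chambers:
            g = g_ch.create_group(str(c.chamber_id))
            g.attrs["condition"] = c.condition
            g.attrs["germinated"] = c.germinated
            g.attrs["germination_time_h"] = (
                _NAN if c.germination_time_h is None else c.germination_time_h)
            g.attrs["mu_h"] = (_NAN if c.growth_fit is None
                               else c.growth_fit.mu_h)
            g.attrs["r_squared"] = (_NAN if c.growth_fit is None
                                    else c.growth_fit.r_squared)
            g.attrs["hgu_um"] = _NAN if c.hgu_um is None else c.hgu_um
            g.attrs["tip_rate_mean_um_h"] = c.tip_rate_mean_um_h
            g.attrs["tip_rate_sd_um_h"] = c.tip_rate_sd_um_h
            g.attrs["n_filtered_tracks"] = c.n_filtered_tracks
            g.attrs["qc_flags"] = ";".join(c.qc_flags)
            series = bundle.series.get(c.chamber_id)
            if series is not None:
                sg = g.create_group("series")
                sg.create_dataset("timestamps_h", data=series.timestamps_h)
                sg.create_dataset("total_length_um",
                                  data=series.total_length_um)
                sg.create_dataset("tip_count", data=series.tip_count)
                sg.create_dataset("coverage_fraction",
                                  data=series.coverage_fraction)
        g_w = f.create_group("wells")
        for w in bundle.wells:
            g = g_w.create_group(str(w.well_id))
            g.attrs["condition"] = w.condition
            g.attrs["blank_value"] = w.blank_value
            g.attrs["lag_phase_h"] = (_NAN if w.lag_phase_h is None
                                      else w.lag_phase_h)
            g.attrs["mu_h"] = _NAN if w.mu_h is None else w.mu_h
            g.attrs["qc_flags"] = ";".join(w.qc_flags)
        g_c = f.create_group("conditions")
        for s in bundle.summaries:
            g = g_c.create_group(f"{s.medium_id}/{s.metric}"
                                 if s.metric else s.medium_id)
            g.attrs["n"] = s.n
            g.attrs["mean"] = s.mean
            g.attrs["sd"] = s.sd

    if bundle.chambers:
        chambers_table(bundle.chambers).to_csv(
            out_dir / "chambers.csv", index=False)
    if bundle.wells:
        wells_table(bundle.wells).to_csv(out_dir / "wells.csv", index=False)
    if bundle.summaries:
        summaries_table(bundle.summaries).to_csv(
            out_dir / "conditions.csv", index=False)
    if bundle.ttests:
        ttests_table(bundle.ttests).to_csv(out_dir / "ttests.csv", index=False)
    if figures:
        _write_figures(bundle, out_dir)
    return h5_path


def load_run(h5_path: str | Path) -> dict:
    """Reload the scalar content of an exported run (audit round-trip)."""
    out: dict = {"chambers": {}, "wells": {}, "conditions": {}}
    with h5py.File(h5_path, "r") as f:
        for cid, g in f["chambers"].items():
            out["chambers"][cid] = dict(g.attrs)
            if "series" in g:
                out["chambers"][cid]["series"] = {
                    k: g["series"][k][()] for k in g["series"]}
        for wid, g in f["wells"].items():
            out["wells"][wid] = dict(g.attrs)

        def visit(name, obj):
            if isinstance(obj, h5py.Group) and "mean" in obj.attrs:
                out["conditions"][name] = dict(obj.attrs)
        f["conditions"].visititems(visit)
    return out


def _write_figures(bundle: RunBundle, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)

    if bundle.series:
        fig, ax = plt.subplots(figsize=(6, 4))
        for cid, series in sorted(bundle.series.items()):
            ax.plot(series.timestamps_h, series.total_length_um, label=cid)
        ax.set_xlabel("time [h]")
        ax.set_ylabel("total mycelium length [um]")
        ax.set_yscale("log")
        if len(bundle.series) <= 10:
            ax.legend(fontsize=6)
        fig.savefig(fig_dir / "growth_curves.png", dpi=120)
        plt.close(fig)

    df = chambers_table(bundle.chambers) if bundle.chambers else pd.DataFrame()
    if not df.empty and df["condition"].nunique() >= 1:
        for metric in ("mu_h", "hgu_um", "germination_time_h",
                       "tip_rate_mean_um_h"):
            groups = [(cond, sub[metric].dropna().to_numpy())
                      for cond, sub in df.groupby("condition")]
            groups = [(c, v) for c, v in groups if v.size]
            if not groups:
                continue
            fig, ax = plt.subplots(figsize=(5, 4))
            ax.boxplot([v for _, v in groups],
                       tick_labels=[c for c, _ in groups])
            ax.set_ylabel(metric)
            fig.savefig(fig_dir / f"box_{metric}.png", dpi=120)
            plt.close(fig)


def write_signal_csv(signals, path: str | Path) -> None:
    """Scattered-light signals to CSV (time_h, well, intensity)."""
    rows = []
    for sig in signals:
        for t, v in zip(sig.timestamps_h, sig.intensity):
            rows.append({"time_h": t, "well": sig.well_id, "intensity": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_signal_csv(path: str | Path):
    """CSV (time_h, well, intensity) -> list of ScatterSignal."""
    from .mtpc import ScatterSignal

    df = pd.read_csv(path)
    return [
        ScatterSignal(well_id=str(well),
                      timestamps_h=sub["time_h"].to_numpy(),
                      intensity=sub["intensity"].to_numpy())
        for well, sub in df.groupby("well", sort=True)
    ]


def write_tracks_csv(tracks, path: str | Path) -> None:
    """Flat per-sample track table (track_id, frame, time_h, length_um)."""
    rows = [
        {"track_id": tr.track_id, "frame": s.frame_index,
         "time_h": s.timestamp_h, "length_um": s.geodesic_length_um}
        for tr in tracks for s in tr.samples
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
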