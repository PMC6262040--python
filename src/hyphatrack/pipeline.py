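"""End-to-end per-chamber analysis: frames -> masks -> skeletons -> metrics.

`analyze_chamber` runs the full image pipeline on one time-lapse stack:
ROI detection (skipped for pre-segmented/clean-mask input), adaptive
binarization, skeletonization, 20 %-coverage truncation, tip tracking with
the four artefact filters, then germination delay, gated log-linear growth
fit, HGU and tip-rate statistics.  Missing preconditions never raise; they
leave the affected metric unset and add a QC flag, so batch runs over
hundreds of chambers always complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import (ChamberResult, MyceliumTimeSeries, assemble_series,
                     fit_growth_rate, germination_delay, hyphal_growth_unit,
                     tip_elongation_rates)
from .segmentation import (BinaryStack, ChamberROI, binarize, coverage_fraction,
                           detect_chamber_roi, skeletonize_mask)
from .skelgraph import SkeletonGraph, build_skeleton_graph
from .stack import TimeLapseStack
from .tracking import (HyphaTrack, OvergrownAtStartError, TrackFilterCriteria,
                       filter_tracks, track_hyphae)


@dataclass
class ChamberAnalysis:
    """Result plus the intermediates worth keeping for audit."""

    result: ChamberResult
    series: MyceliumTimeSeries | None = None
    graphs: list[SkeletonGraph] = field(default_factory=list)
    tracks: list[HyphaTrack] = field(default_factory=list)
    filtered_tracks: list[HyphaTrack] = field(default_factory=list)
    stop_index: int | None = None


def analyze_chamber(stack: TimeLapseStack, *,
                    chamber_id: str | None = None,
                    condition: str = "",
                    use_clean_masks: bool = False,
                    expected_dims_um: tuple[float, float] = (90.0, 40.0),
                    coverage_threshold: float = 0.2,
                    criteria: TrackFilterCriteria | None = None,
                    r2_gate: float = 0.9,
                    min_fit_points: int = 5,
                    smooth_window: int = 5,
                    block_size: int = 51,
                    threshold_offset: float = 10.0,
                    prune_spur_um: float = 0.2,
                    track: bool = True) -> ChamberAnalysis:
    """Run the whole single-chamber pipeline on a stack."""
    criteria = criteria or TrackFilterCriteria()
    chamber_id = chamber_id or stack.stack_id
    result = ChamberResult(chamber_id=chamber_id, condition=condition)
    analysis = ChamberAnalysis(result=result)
    px = stack.pixel_size_um

    if use_clean_masks:
        if stack.clean_masks is None:
            raise ValueError("stack carries no clean masks")
        roi = ChamberROI.full_frame(stack.frame_shape)
        masks = np.asarray(stack.clean_masks, dtype=bool)
        binary = BinaryStack(masks=masks, roi=roi,
                             timestamps_h=stack.timestamps_h,
                             pixel_size_um=px,
                             provenance={"source": "clean_masks"})
    else:
        try:
            roi = detect_chamber_roi(stack, expected_dims_um)
        except Exception as err:  # noqa: BLE001 - surfaced as QC flag
            result.qc_flags.append(f"roi: {err}")
            return analysis
        binary = binarize(stack, roi, block_size=block_size,
                          offset=threshold_offset)
        result.qc_flags.extend(binary.qc_flags)

    coverages = np.array([coverage_fraction(m, binary.roi)
                          for m in binary.masks])
    try:
        stop = _stop_index(coverages, coverage_threshold)
    except OvergrownAtStartError as err:
        result.qc_flags.append(str(err))
        return analysis
    analysis.stop_index = stop
    if stop == len(binary.masks) - 1 and coverages[stop] < coverage_threshold:
        # mycelium still below the tracking stop when frames ran out —
        # density-gated metrics (HGU) may not have plateaued yet
        result.qc_flags.append("immature: coverage stop not reached")

    prune_px = int(round(prune_spur_um / px))
    graphs = []
    for k in range(stop + 1):
        skel = skeletonize_mask(binary.masks[k], prune_spur_px=prune_px)
        graphs.append(build_skeleton_graph(
            skel, float(stack.timestamps_h[k]), px, frame_index=k))
    analysis.graphs = graphs

    analysis.series = assemble_series(graphs, coverages, stop)
    if track:
        analysis.tracks = track_hyphae(
            graphs,
            max_elongation_rate_um_h=criteria.max_elongation_rate_um_h)
        analysis.filtered_tracks = filter_tracks(analysis.tracks, criteria)
        result.n_filtered_tracks = len(analysis.filtered_tracks)

        result.germination_time_h = germination_delay(
            analysis.filtered_tracks)
        if result.germination_time_h is None:
            result.qc_flags.append("no trackable hypha (non-germinated)")
            return analysis

    result.growth_fit = fit_growth_rate(analysis.series, r2_gate=r2_gate,
                                        min_fit_points=min_fit_points)
    if result.growth_fit is None:
        result.qc_flags.append("no window passed the R^2 gate")
    result.hgu_um = hyphal_growth_unit(analysis.series, result.growth_fit,
                                       smooth_window=smooth_window)
    if result.growth_fit is not None and result.hgu_um is None:
        result.qc_flags.append("no tips within the fit window")

    if track:
        rate_stats = tip_elongation_rates(analysis.filtered_tracks)
        result.tip_rate_mean_um_h = rate_stats.mean_um_h
        result.tip_rate_sd_um_h = rate_stats.sd_um_h
    if analysis.series.tip_count[-1] < 10:
        # curation cue: density-gated statistics (HGU) want a developed,
        # branched mycelium, not a sparse few-hypha chamber
        result.qc_flags.append("underdeveloped: fewer than 10 tips at end")
    return analysis


def _stop_index(coverages: np.ndarray, threshold: float) -> int:
    if coverages[0] >= threshold:
        raise OvergrownAtStartError(
            f"overgrown at start: coverage {coverages[0]:.3f} >= {threshold}")
    crossing = np.flatnonzero(coverages >= threshold)
    return int(crossing[0] - 1) if crossing.size else len(coverages) - 1
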