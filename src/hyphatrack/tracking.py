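"""Spatiotemporal tracking of hyphal tips over skeleton-graph sequences.

Tips (skeleton endpoints) are matched frame-to-frame by greedy nearest
neighbour within a distance gate derived from the maximum biologically
plausible elongation rate.  Each track records the tip's geodesic length
along the current skeleton from its birth anchor, and tracks are filtered
by the four artefact rules used for hyphal statistics:

(a) at least 5 consecutive time points,
(b) final length strictly greater than 10 um,
(c) total growth of at least 5 um,
(d) no frame-to-frame elongation rate above 100 um/h.

Tracking stops at 20 % chamber coverage to avoid erroneous segmentations
of densely packed mycelium.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .segmentation import BinaryStack, ChamberROI, coverage_fraction
from .skelgraph import SkeletonGraph

_SQRT2 = np.sqrt(2.0)


@dataclass
class TrackSample:
    frame_index: int
    timestamp_h: float
    tip_pos: tuple[int, int]          # (row, col) pixel
    geodesic_length_um: float


@dataclass
class HyphaTrack:
    track_id: int
    anchor_pos: tuple[float, float]   # (row, col) pixel, fixed at birth
    samples: list[TrackSample] = field(default_factory=list)
    rejected_by: str | None = None    # first violated filter rule, if any

    @property
    def birth_frame(self) -> int:
        return self.samples[0].frame_index

    @property
    def last_frame(self) -> int:
        return self.samples[-1].frame_index

    @property
    def birth_time_h(self) -> float:
        return self.samples[0].timestamp_h

    @property
    def initial_length_um(self) -> float:
        return self.samples[0].geodesic_length_um

    @property
    def final_length_um(self) -> float:
        return self.samples[-1].geodesic_length_um

    @property
    def lengths_um(self) -> np.ndarray:
        return np.array([s.geodesic_length_um for s in self.samples])

    @property
    def times_h(self) -> np.ndarray:
        return np.array([s.timestamp_h for s in self.samples])

    def instantaneous_rates(self) -> np.ndarray:
        """Frame-to-frame elongation rates, um/h."""
        if len(self.samples) < 2:
            return np.empty(0)
        return np.diff(self.lengths_um) / np.diff(self.times_h)


@dataclass
class TrackFilterCriteria:
    min_consecutive_frames: int = 5
    min_final_length_um: float = 10.0
    min_total_growth_um: float = 5.0
    max_elongation_rate_um_h: float = 100.0

    def __post_init__(self) -> None:
        if min(self.min_consecutive_frames, self.min_final_length_um,
               self.min_total_growth_um, self.max_elongation_rate_um_h) <= 0:
            raise ValueError("all filter criteria must be positive")


class OvergrownAtStartError(RuntimeError):
    pass


def truncate_at_coverage(binary: BinaryStack | np.ndarray,
                         roi: ChamberROI | None = None,
                         threshold: float = 0.2) -> int:
    """Largest frame index f with coverage < threshold on all frames <= f.

    Raises :class:`OvergrownAtStartError` when the first frame already
    reaches the threshold.
    """
    if isinstance(binary, BinaryStack):
        masks, roi = binary.masks, binary.roi
    else:
        masks = binary
        if roi is None:
            raise ValueError("roi required when passing a bare mask array")
    cov = [coverage_fraction(m, roi) for m in masks]
    if cov[0] >= threshold:
        raise OvergrownAtStartError(
            f"overgrown at start: coverage {cov[0]:.3f} >= {threshold}")
    for f, c in enumerate(cov):
        if c >= threshold:
            return f - 1
    return len(cov) - 1


def _pixel_geodesics(graph: SkeletonGraph, tip_pixels: list[tuple[int, int]],
                     anchor_pixels: list[tuple[float, float]]) -> np.ndarray:
    """Geodesic um distances along the skeleton, tips x anchors.

    Anchors are mapped to their nearest skeleton pixel; unreachable pairs
    (disconnected components) fall back to the Euclidean distance.
    """
    skel = graph.skeleton
    coords = np.argwhere(skel)
    n = len(coords)
    idx = {tuple(p): i for i, p in enumerate(coords)}
    rows, cols, w = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        shifted = coords + (dr, dc)
        ok = (shifted[:, 0] >= 0) & (shifted[:, 0] < skel.shape[0]) & \
             (shifted[:, 1] >= 0) & (shifted[:, 1] < skel.shape[1])
        ok[ok] = skel[shifted[ok, 0], shifted[ok, 1]]
        src = np.flatnonzero(ok)
        dst = [idx[tuple(p)] for p in shifted[src]]
        rows.extend(src)
        cols.extend(dst)
        w.extend([_SQRT2 if dr and dc else 1.0] * len(src))
    adj = coo_matrix((w, (rows, cols)), shape=(n, n)).tocsr()
    tree = cKDTree(coords)
    anchor_idx = tree.query(np.asarray(anchor_pixels))[1] if anchor_pixels else []
    tip_idx = [idx[p] for p in tip_pixels]
    if not tip_idx or len(anchor_idx) == 0:
        return np.zeros((len(tip_idx), len(anchor_idx)))
    dist = dijkstra(adj, directed=False, indices=tip_idx)
    out = dist[:, anchor_idx] * graph.pixel_size_um
    # fallback for disconnected anchor/tip pairs
    bad = ~np.isfinite(out)
    if bad.any():
        tips_arr = np.asarray(tip_pixels, dtype=float)
        anch_arr = coords[anchor_idx].astype(float)
        eucl = np.linalg.norm(tips_arr[:, None, :] - anch_arr[None, :, :],
                              axis=-1) * graph.pixel_size_um
        out[bad] = eucl[bad]
    return out


def track_hyphae(graphs: list[SkeletonGraph],
                 max_elongation_rate_um_h: float = 100.0,
                 match_slack_px: float = 2.0) -> list[HyphaTrack]:
    """Track skeleton endpoints through a time-ordered graph sequence.

    Matching is greedy nearest neighbour within a gate of
    ``max_rate * dt + slack`` (deterministic tie-break by tip index).
    New tips open tracks anchored at the nearest junction of their birth
    frame (skeleton centroid when no junction exists yet); unmatched tips
    terminate their track — tracks are never gap-filled.
    """
    tracks: list[HyphaTrack] = []
    active: list[HyphaTrack] = []
    prev_time: float | None = None
    for graph in graphs:
        px = graph.pixel_size_um
        tips = [n.pos for n in graph.endpoints]
        dt = (graph.timestamp_h - prev_time) if prev_time is not None else None

        assigned: dict[int, HyphaTrack] = {}
        if active and tips and dt is not None:
            gate_um = max_elongation_rate_um_h * dt + match_slack_px * px
            prev_pos = np.array([t.samples[-1].tip_pos for t in active], float)
            cur_pos = np.asarray(tips, dtype=float)
            d_um = np.linalg.norm(
                prev_pos[:, None, :] - cur_pos[None, :, :], axis=-1) * px
            pairs = sorted(
                (d_um[i, j], i, j)
                for i in range(len(active)) for j in range(len(tips))
                if d_um[i, j] <= gate_um)
            used_prev: set[int] = set()
            for d, i, j in pairs:
                if i in used_prev or j in assigned:
                    continue
                used_prev.add(i)
                assigned[j] = active[i]

        junctions = [n.pos for n in graph.junctions]
        if graph.skeleton is not None and graph.skeleton.any():
            centroid = tuple(np.argwhere(graph.skeleton).mean(axis=0))
        else:
            centroid = (0.0, 0.0)

        new_active: list[HyphaTrack] = []
        track_of_tip: list[HyphaTrack] = []
        for j, pos in enumerate(tips):
            if j in assigned:
                track = assigned[j]
            else:
                if junctions:
                    jd = [np.hypot(q[0] - pos[0], q[1] - pos[1]) for q in junctions]
                    anchor = junctions[int(np.argmin(jd))]
                else:
                    anchor = centroid
                track = HyphaTrack(track_id=len(tracks),
                                   anchor_pos=(float(anchor[0]), float(anchor[1])))
                tracks.append(track)
            track_of_tip.append(track)
            new_active.append(track)

        if tips:
            geod = _pixel_geodesics(
                graph, tips, [t.anchor_pos for t in track_of_tip])
            for j, track in enumerate(track_of_tip):
                track.samples.append(TrackSample(
                    frame_index=graph.frame_index,
                    timestamp_h=graph.timestamp_h,
                    tip_pos=tips[j],
                    geodesic_length_um=float(geod[j, j])))
        active = new_active
        prev_time = graph.timestamp_h
    return tracks


_RULE_ORDER = ("a", "b", "c", "d")


def filter_tracks(tracks: list[HyphaTrack],
                  criteria: TrackFilterCriteria | None = None
                  ) -> list[HyphaTrack]:
    """Apply the four artefact filters; annotate rejects, return keepers.

    Rule (b) is strict (> min_final_length_um); (c) and (d) are inclusive.
    The function is idempotent and per-track, hence order independent.
    """
    criteria = criteria or TrackFilterCriteria()
    kept: list[HyphaTrack] = []
    for track in tracks:
        rule = _first_violation(track, criteria)
        track.rejected_by = rule
        if rule is None:
            kept.append(track)
    return kept


def _first_violation(track: HyphaTrack,
                     c: TrackFilterCriteria) -> str | None:
    if len(track.samples) < c.min_consecutive_frames:
        return "a"
    if not track.final_length_um > c.min_final_length_um:
        return "b"
    if not (track.final_length_um - track.initial_length_um
            ) >= c.min_total_growth_um:
        return "c"
    rates = track.instantaneous_rates()
    if rates.size and rates.max() > c.max_elongation_rate_um_h:
        return "d"
    return None
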