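"""Chamber detection, binarization, skeletonization and coverage.

The raw-image stages of the pipeline: find the cultivation-chamber region
of interest once on the first frame (chambers are static, so no image
registration is needed), adaptively threshold each frame inside the ROI,
thin the foreground to a one-pixel skeleton, and measure how much of the
chamber the mycelium covers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.morphology import skeletonize

from .stack import TimeLapseStack


@dataclass
class ChamberROI:
    """Axis-aligned chamber rectangle, half-open pixel intervals, 0-based."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    detection_score: float = 1.0

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI must have positive area")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.row_stop - self.row_start, self.col_stop - self.col_start)

    @property
    def area_px(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def center(self) -> tuple[float, float]:
        return ((self.row_start + self.row_stop) / 2.0,
                (self.col_start + self.col_stop) / 2.0)

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.row_start:self.row_stop, self.col_start:self.col_stop]

    @classmethod
    def full_frame(cls, shape: tuple[int, int]) -> "ChamberROI":
        return cls(0, shape[0], 0, shape[1], detection_score=1.0)


@dataclass
class BinaryStack:
    """Per-frame boolean masks restricted to the ROI, with provenance."""

    masks: np.ndarray            # (T, h, w) bool, ROI-shaped
    roi: ChamberROI
    timestamps_h: np.ndarray
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)
    qc_flags: list[str] = field(default_factory=list)


class ChamberNotFoundError(RuntimeError):
    pass


def detect_chamber_roi(stack: TimeLapseStack,
                       expected_dims_um: tuple[float, float] = (90.0, 40.0),
                       min_score: float = 0.2) -> ChamberROI:
    """Locate the chamber rectangle on the first frame.

    The chamber walls produce strong intensity edges; the detector scores
    every placement of a rectangle with the expected calibrated dimensions
    (width x height in um) by the summed gradient magnitude along its
    border, using separable row/column gradient profiles.  The best-scoring
    placement is returned and reused for all frames.

    Raises :class:`ChamberNotFoundError` when the frame is too small to
    hold the rectangle or the normalized border response is below
    ``min_score`` (e.g. a pure-noise frame).
    """
    frame = np.asarray(stack.frames[0], dtype=float)
    px = stack.pixel_size_um
    w_px = int(round(expected_dims_um[0] / px))
    h_px = int(round(expected_dims_um[1] / px))
    rows, cols = frame.shape
    if h_px > rows or w_px > cols or w_px <= 0 or h_px <= 0:
        raise ChamberNotFoundError("chamber not found: frame smaller than chamber")
    if h_px == rows and w_px == cols:
        return ChamberROI(0, rows, 0, cols, detection_score=1.0)

    gy = np.abs(np.diff(frame, axis=0)).sum(axis=1)   # edge response per row gap
    gx = np.abs(np.diff(frame, axis=1)).sum(axis=0)   # edge response per col gap

    def best_offset(profile: np.ndarray, extent: int, limit: int) -> tuple[int, float]:
        # response of placing [o, o + extent) — edges just outside the ROI
        scores = []
        for o in range(0, limit - extent + 1):
            top = profile[o - 1] if o >= 1 else 0.0
            bot = profile[o + extent - 1] if o + extent - 1 < len(profile) else 0.0
            scores.append(top + bot)
        scores = np.asarray(scores)
        o = int(np.argmax(scores))
        denom = profile.sum() + 1e-12
        return o, float(scores[o] / denom)

    r0, score_r = best_offset(gy, h_px, rows)
    c0, score_c = best_offset(gx, w_px, cols)
    score = float(np.sqrt(max(score_r, 0.0) * max(score_c, 0.0)))
    if score < min_score:
        raise ChamberNotFoundError(
            f"chamber not found: border response {score:.3f} < {min_score}")
    return ChamberROI(r0, r0 + h_px, c0, c0 + w_px, detection_score=min(score, 1.0))


def binarize(stack: TimeLapseStack, roi: ChamberROI,
             block_size: int = 51, offset: float = 10.0,
             min_object_um2: float = 1.0,
             polarity: str = "auto") -> BinaryStack:
    """Adaptive local-mean threshold of each frame inside the ROI.

    Pixels darker (default polarity) than their local neighbourhood mean
    (block ``block_size``) by more than ``offset`` intensity units are
    foreground; connected components smaller than ``min_object_um2`` are
    removed and a morphological closing bridges 1-px gaps.  The offset
    must sit between the blur-halo amplitude and the object contrast.
    ``polarity='auto'`` decides per stack whether hyphae are darker or
    brighter than the background (minority phase vs. the local mean).
    A constant frame yields an empty mask and a QC flag.
    """
    if block_size % 2 == 0:
        block_size += 1
    px = stack.pixel_size_um
    min_px = max(1, int(round(min_object_um2 / (px * px))))
    masks = np.zeros((stack.n_frames,) + roi.shape, dtype=bool)
    flags: list[str] = []

    dark = _polarity_is_dark(roi.crop(stack.frames[-1]), polarity)
    for k in range(stack.n_frames):
        img = np.asarray(roi.crop(stack.frames[k]), dtype=float)
        if np.ptp(img) == 0:
            flags.append(f"frame {k}: degenerate intensity range")
            continue
        local = threshold_local(img, block_size, method="mean")
        mask = (img < local - offset) if dark else (img > local + offset)
        if min_px > 1:
            mask = _remove_small(mask, min_px)
        mask = ndimage.binary_closing(mask, structure=np.ones((3, 3)))
        masks[k] = mask
    return BinaryStack(
        masks=masks, roi=roi, timestamps_h=stack.timestamps_h,
        pixel_size_um=px,
        provenance={"block_size": block_size, "offset": offset,
                    "min_object_um2": min_object_um2,
                    "polarity": "dark" if dark else "bright"},
        qc_flags=flags,
    )


def _polarity_is_dark(img: np.ndarray, polarity: str) -> bool:
    if polarity == "dark":
        return True
    if polarity == "bright":
        return False
    if polarity != "auto":
        raise ValueError("polarity must be 'dark', 'bright' or 'auto'")
    img = np.asarray(img, dtype=float)
    # hyphae are the minority phase: a dark minority drags the mean below
    # the median, a bright minority pushes it above
    return bool(np.mean(img) <= np.median(img))


def _remove_small(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(labels, keep)


def skeletonize_mask(mask: np.ndarray, prune_spur_px: int = 0) -> np.ndarray:
    """Topology-preserving thinning to a 1-px, 8-connected skeleton.

    Isolated single pixels (no 8-neighbours) are removed; an empty mask
    yields an empty skeleton.  ``prune_spur_px > 0`` additionally removes
    terminal spurs (endpoint-to-junction chains) up to that pixel length —
    boundary-bump artefacts of thinning a tube of finite width; genuine
    whole hyphae (endpoint-to-endpoint components) are never pruned.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros_like(mask)
    skel = skeletonize(mask)
    neighbours = ndimage.convolve(skel.astype(np.uint8),
                                  np.ones((3, 3), dtype=np.uint8),
                                  mode="constant") - skel
    skel &= ~((neighbours == 0) & skel)
    skel = _enforce_one_px(skel)
    if prune_spur_px > 0:
        skel = _prune_spurs(skel, prune_spur_px)
    return skel


def _enforce_one_px(skel: np.ndarray) -> np.ndarray:
    """Delete simple points until no 2x2 foreground block remains.

    Zhang thinning occasionally leaves 2x2 blocks; removing a corner whose
    8-neighbourhood stays connected (Hilditch crossing number 1) restores
    the strict 1-px-width property without changing topology.
    """
    eight = np.ones((3, 3), dtype=int)

    def simple(r: int, c: int) -> bool:
        patch = np.zeros((3, 3), dtype=bool)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr, dc) != (0, 0) and 0 <= rr < skel.shape[0] \
                        and 0 <= cc < skel.shape[1]:
                    patch[dr + 1, dc + 1] = skel[rr, cc]
        _, n_comp = ndimage.label(patch, structure=eight)
        return n_comp == 1 and patch.sum() > 1

    for _ in range(4):
        blocks = np.argwhere(skel[:-1, :-1] & skel[1:, :-1]
                             & skel[:-1, 1:] & skel[1:, 1:])
        if blocks.size == 0:
            break
        changed = False
        for r, c in blocks:
            for dr, dc in ((0, 0), (0, 1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if skel[rr, cc] and simple(rr, cc):
                    skel[rr, cc] = False
                    changed = True
                    break
        if not changed:
            break
    return skel


def _prune_spurs(skel: np.ndarray, max_len_px: int,
                 max_iter: int = 3) -> np.ndarray:
    """Remove endpoint chains of <= max_len_px pixels ending in a junction."""
    kernel = np.ones((3, 3), dtype=np.uint8)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    h, w = skel.shape
    for _ in range(max_iter):
        deg = ndimage.convolve(skel.astype(np.uint8), kernel,
                               mode="constant") - skel
        endpoints = np.argwhere(skel & (deg == 1))
        removed_any = False
        for r, c in endpoints:
            if not skel[r, c]:
                continue
            path = [(r, c)]
            prev = None
            cur = (int(r), int(c))
            hit_junction = False
            while len(path) <= max_len_px:
                nbrs = [
                    (cur[0] + dr, cur[1] + dc) for dr, dc in offsets
                    if 0 <= cur[0] + dr < h and 0 <= cur[1] + dc < w
                    and skel[cur[0] + dr, cur[1] + dc]
                    and (cur[0] + dr, cur[1] + dc) != prev
                ]
                if len(nbrs) != 1:
                    hit_junction = len(nbrs) > 1
                    break
                nxt = nbrs[0]
                if deg[nxt] >= 3:
                    hit_junction = True
                    break
                prev, cur = cur, nxt
                path.append(cur)
            if hit_junction and len(path) <= max_len_px:
                for p in path:
                    skel[p] = False
                removed_any = True
        if not removed_any:
            break
        # pruning may leave fresh isolated pixels
        deg = ndimage.convolve(skel.astype(np.uint8), kernel,
                               mode="constant") - skel
        skel &= ~((deg == 0) & skel)
    return skel


def coverage_fraction(mask: np.ndarray, roi: ChamberROI) -> float:
    """Foreground fraction of the chamber ROI, in [0, 1]."""
    if roi.area_px <= 0:
        raise ValueError("ROI has zero area")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != roi.shape:
        raise ValueError("mask must be ROI-shaped")
    return float(mask.sum()) / float(roi.area_px)
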