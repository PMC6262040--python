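"""Skeleton masks as graphs: endpoints, junctions and branch edges.

A 1-px skeleton is turned into a graph whose nodes are endpoint pixels
(one 8-neighbour) and junction pixels (three or more), and whose edges are
the maximal degree-2 pixel chains between them.  Edge lengths use the
standard chain metric — 1 px for orthogonal steps, sqrt(2) px for diagonal
steps — scaled by the pixel calibration, which is the single source of
truth for total mycelium length and tip count downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_SQRT2 = math.sqrt(2.0)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class SkelNode:
    node_id: int
    pos: tuple[int, int]          # (row, col)
    kind: str                     # 'endpoint', 'junction' or 'anchor' (loop)


@dataclass
class SkelEdge:
    node_a: int
    node_b: int
    path: np.ndarray              # (N, 2) ordered pixel coordinates
    length_um: float


@dataclass
class SkeletonGraph:
    frame_index: int
    timestamp_h: float
    pixel_size_um: float
    nodes: list[SkelNode] = field(default_factory=list)
    edges: list[SkelEdge] = field(default_factory=list)
    skeleton: np.ndarray | None = None

    @property
    def total_length_um(self) -> float:
        return float(sum(e.length_um for e in self.edges))

    @property
    def tip_count(self) -> int:
        return sum(1 for n in self.nodes if n.kind == "endpoint")

    @property
    def endpoints(self) -> list[SkelNode]:
        return [n for n in self.nodes if n.kind == "endpoint"]

    @property
    def junctions(self) -> list[SkelNode]:
        return [n for n in self.nodes if n.kind == "junction"]

    def degree(self, node_id: int) -> int:
        d = 0
        for e in self.edges:
            if e.node_a == node_id:
                d += 1
            if e.node_b == node_id:
                d += 1
        return d


def _chain_length_um(path: np.ndarray, pixel_size_um: float) -> float:
    if len(path) < 2:
        return 0.0
    steps = np.abs(np.diff(path, axis=0))
    diag = (steps.max(axis=1) > 0) & (steps.min(axis=1) > 0)
    return float((np.where(diag, _SQRT2, 1.0).sum()) * pixel_size_um)


def build_skeleton_graph(skeleton: np.ndarray, timestamp_h: float,
                         pixel_size_um: float,
                         frame_index: int = 0) -> SkeletonGraph:
    """Trace a 1-px skeleton into nodes and edges.

    Closed loops without any endpoint/junction pixel are decomposed by
    inserting an ``anchor`` node carrying a self-loop edge.
    """
    skeleton = np.asarray(skeleton, dtype=bool)
    graph = SkeletonGraph(frame_index=frame_index, timestamp_h=timestamp_h,
                          pixel_size_um=pixel_size_um, skeleton=skeleton)
    if not skeleton.any():
        return graph

    deg = ndimage.convolve(skeleton.astype(np.uint8),
                           np.ones((3, 3), dtype=np.uint8),
                           mode="constant") - skeleton
    node_mask = skeleton & (deg != 2)
    node_coords = [tuple(p) for p in np.argwhere(node_mask)]
    node_ids: dict[tuple[int, int], int] = {}
    for p in node_coords:
        d = deg[p]
        if d == 0:
            continue  # isolated pixel; removed upstream, skip defensively
        kind = "endpoint" if d == 1 else "junction"
        node_ids[p] = len(graph.nodes)
        graph.nodes.append(SkelNode(len(graph.nodes), p, kind))

    h, w = skeleton.shape

    def neighbours(p: tuple[int, int]):
        r, c = p
        for dr, dc in _OFFSETS:
            q = (r + dr, c + dc)
            if 0 <= q[0] < h and 0 <= q[1] < w and skeleton[q]:
                yield q

    used_steps: set[tuple[tuple[int, int], tuple[int, int]]] = set()
    visited_chain: set[tuple[int, int]] = set()
    n_skel_px = int(skeleton.sum())

    def trace(start: tuple[int, int], first: tuple[int, int]) -> None:
        if (start, first) in used_steps:
            return
        used_steps.add((start, first))
        path = [start, first]
        prev, cur = start, first
        while cur not in node_ids:
            visited_chain.add(cur)
            nxt = [q for q in neighbours(cur) if q != prev]
            if len(nxt) != 1:
                # ambiguous chain pixel (rare thinning artefact): prefer a
                # step continuing away from prev; fall back to first option
                nxt = [q for q in nxt if q not in path[-3:]] or nxt
                if not nxt:
                    break
            prev, cur = cur, nxt[0]
            path.append(cur)
            if len(path) > n_skel_px + 2:
                break  # safety net
        if cur in node_ids:
            used_steps.add((cur, prev))
            graph.edges.append(SkelEdge(
                node_ids[start], node_ids[cur], np.asarray(path),
                _chain_length_um(np.asarray(path), pixel_size_um)))

    for p in node_coords:
        if p not in node_ids:
            continue
        for q in neighbours(p):
            trace(p, q)

    # remaining deg-2 pixels belong to pure cycles: insert anchor nodes
    leftover = skeleton & (deg == 2)
    for p in node_coords:
        leftover[p] = False
    for p in visited_chain:
        leftover[p] = False
    while leftover.any():
        start = tuple(np.argwhere(leftover)[0])
        node_ids[start] = len(graph.nodes)
        graph.nodes.append(SkelNode(len(graph.nodes), start, "anchor"))
        first = next(q for q in neighbours(start) if leftover[q] or q == start)
        path = [start, first]
        prev, cur = start, first
        leftover[start] = False
        while cur != start:
            leftover[cur] = False
            nxt = [q for q in neighbours(cur) if q != prev]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            path.append(cur)
        graph.edges.append(SkelEdge(
            node_ids[start], node_ids[start], np.asarray(path),
            _chain_length_um(np.asarray(path), pixel_size_um)))
    return graph
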