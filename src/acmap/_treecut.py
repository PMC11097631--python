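"""Hybrid dynamic tree cut for dendrograms over small distance matrices.

Adaptive branch decomposition in the spirit of the dynamic hybrid
method: branches of the dendrogram are promoted to clusters when they
are large enough, internally tight (core scatter) and well separated
from their surroundings (gap to the merge height), with a PAM-like
stage assigning leftover objects to sufficiently close clusters.  The
``deep_split`` sensitivity (0-4, fractional allowed) maps onto the
core-scatter/gap thresholds by linear interpolation.

Label 0 marks unassigned objects; clusters are numbered from 1 in
decreasing size order.
"""

from __future__ import annotations

import numpy as np

_DEEPSPLIT_GRID = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
_CORE_SCATTER_GRID = np.array([0.64, 0.73, 0.82, 0.91, 0.95])


def _split_params(deep_split: float):
    if not 0.0 <= deep_split <= 4.0:
        raise ValueError("deep_split must be within [0, 4]")
    max_core_scatter = float(
        np.interp(deep_split, _DEEPSPLIT_GRID, _CORE_SCATTER_GRID)
    )
    min_gap = (1.0 - max_core_scatter) * 0.75
    return max_core_scatter, min_gap


def _core_size(n: int, min_cluster_size: int) -> int:
    return min(n, min_cluster_size + int(np.sqrt(max(n - min_cluster_size, 0))))


class _Branch:
    __slots__ = ("leaves",)

    def __init__(self, leaves):
        self.leaves = list(leaves)  # in join order


def cutree_hybrid(
    linkage: np.ndarray,
    dist: np.ndarray,
    deep_split: float = 2.5,
    min_cluster_size: int = 2,
    cut_height: float | None = None,
    pam_stage: bool = True,
) -> np.ndarray:
    """Cut a scipy linkage into clusters; returns labels (0 = unassigned)."""
    linkage = np.asarray(linkage, dtype=float)
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValueError("dist must be square")
    if linkage.shape[0] != n - 1:
        raise ValueError("linkage does not match distance matrix size")
    heights = linkage[:, 2]
    ref_height = float(np.percentile(heights, 5.0))
    max_height = float(heights.max())
    if cut_height is None:
        cut_height = ref_height + 0.99 * (max_height - ref_height)
    span = cut_height - ref_height

    def norm(h):
        if span <= 0:
            return 0.0
        return max((h - ref_height) / span, 0.0)

    max_core_scatter, min_gap = _split_params(deep_split)

    def core_scatter(leaves) -> float:
        core = leaves[: _core_size(len(leaves), min_cluster_size)]
        if len(core) < 2:
            return 0.0
        idx = np.asarray(core)
        sub = dist[np.ix_(idx, idx)]
        m = len(core)
        return float(sub[np.triu_indices(m, k=1)].mean())

    def qualifies(branch: _Branch, merge_height: float) -> bool:
        if len(branch.leaves) < min_cluster_size:
            return False
        scatter = norm(core_scatter(branch.leaves))
        gap = norm(merge_height) - scatter
        return scatter <= max_core_scatter and gap >= min_gap

    # walk merges bottom-up; nodes 0..n-1 are leaves, n+k is merge k
    nodes: dict[int, _Branch | None] = {i: _Branch([i]) for i in range(n)}
    clusters: list[list[int]] = []
    tops: list[tuple[_Branch, float]] = []  # branches detached at cut_height

    for k in range(n - 1):
        a, b = int(linkage[k, 0]), int(linkage[k, 1])
        h = heights[k]
        ba, bb = nodes.pop(a), nodes.pop(b)
        if h > cut_height:
            for br in (ba, bb):
                if br is not None and br.leaves:
                    tops.append((br, min(h, max_height)))
            nodes[n + k] = None
            continue
        if ba is None or bb is None:
            # one side already resolved into locked clusters
            nodes[n + k] = ba if bb is None else bb
            continue
        qa, qb = qualifies(ba, h), qualifies(bb, h)
        if qa and qb:
            clusters.append(list(ba.leaves))
            clusters.append(list(bb.leaves))
            nodes[n + k] = None
        else:
            # keep growing: larger branch keeps its join order first
            first, second = (ba, bb) if len(ba.leaves) >= len(bb.leaves) else (bb, ba)
            nodes[n + k] = _Branch(first.leaves + second.leaves)

    for br in nodes.values():
        if br is not None and br.leaves:
            tops.append((br, cut_height))
    for br, h in tops:
        if qualifies(br, max(h, cut_height)):
            clusters.append(list(br.leaves))

    labels = np.zeros(n, dtype=int)
    clusters.sort(key=lambda c: (-len(c), min(c)))
    for lab, members in enumerate(clusters, start=1):
        labels[np.asarray(members)] = lab

    if pam_stage and clusters:
        unassigned = np.nonzero(labels == 0)[0]
        for i in unassigned:
            best_lab, best_d = 0, np.inf
            for lab, members in enumerate(clusters, start=1):
                d = float(dist[i, np.asarray(members)].mean())
                if d < best_d:
                    best_lab, best_d = lab, d
            if best_d < cut_height:
                labels[i] = best_lab
    return labels
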