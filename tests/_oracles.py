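"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's spatial-indexing code paths:
all-pairs distance scans, union-find connected components and an
exhaustive greedy QT clustering, so that the fast implementations are
checked against first-principles definitions.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def brute_force_edges(xy: np.ndarray, ids: np.ndarray, radius: float) -> set:
    """All unordered id pairs at Euclidean distance <= radius (closed)."""
    d = cdist(xy, xy)
    edges = set()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= radius:
                edges.add(frozenset((int(ids[i]), int(ids[j]))))
    return edges


def union_find_components(ids, edges) -> set:
    """Connected components via union-find; returns a set of frozensets."""
    parent = {int(i): int(i) for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for e in edges:
        a, b = tuple(e)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps = {}
    for i in parent:
        comps.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in comps.values()}


def violating_same_channel_pairs(xy, channels, radius: float) -> list:
    """All same-channel pairs strictly closer than radius (audit helper)."""
    d = cdist(xy, xy)
    out = []
    n = len(xy)
    for i in range(n):
        for j in range(i + 1, n):
            if channels[i] == channels[j] and d[i, j] < radius:
                out.append((i, j))
    return out


def greedy_qt_oracle(dmat: np.ndarray, ids, threshold: float):
    """Exhaustive greedy QT clustering on a precomputed distance matrix.

    Among unassigned items, the one with the most within-threshold
    unassigned neighbours (ties: lowest id) is extracted as a centre
    together with those neighbours.  Returns a list of (center_id,
    frozenset(member_ids)) in extraction order.
    """
    ids = [int(i) for i in ids]
    unassigned = list(range(len(ids)))
    clusters = []
    while unassigned:
        counts = []
        for k in unassigned:
            c = sum(
                1
                for j in unassigned
                if j != k and dmat[k, j] <= threshold
            )
            counts.append((-c, ids[k], k))
        counts.sort()
        _, _, best = counts[0]
        members = [best] + [
            j for j in unassigned if j != best and dmat[best, j] <= threshold
        ]
        clusters.append((ids[best], frozenset(ids[m] for m in members)))
        unassigned = [k for k in unassigned if k not in members]
    return clusters
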