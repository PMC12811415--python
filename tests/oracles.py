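"""Independent brute-force oracles used to check the package's fast paths.

Everything here is deliberately naive (full distance matrices, ray casting,
all-pairs scans, union-find) and shares no code with the implementations it
checks.
"""

from __future__ import annotations

import numpy as np


def distance_matrix(points: np.ndarray) -> np.ndarray:
    diff = points[:, None, :] - points[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def brute_neighbors(points: np.ndarray, center: int, eps: float) -> np.ndarray:
    """O(n) linear distance scan; center included."""
    d = np.sqrt(((points - points[center]) ** 2).sum(axis=1))
    return np.flatnonzero(d <= eps)


def brute_dbscan_sets(points: np.ndarray, eps: float, mnm: int):
    """Reference clustering as order-independent sets.

    Returns (core_mask, core_partition, border_mask, noise_mask) where
    core_partition is a frozenset of frozensets of core indices (the
    connected components of the core-core eps graph). Border points are the
    non-core points within eps of some core point; everything else is noise.
    """
    n = len(points)
    d = distance_matrix(points)
    adj = d <= eps
    core = adj.sum(axis=1) >= mnm  # self counted (diagonal is True)
    # components of the core subgraph by BFS
    comp = np.full(n, -1)
    cid = 0
    for start in range(n):
        if not core[start] or comp[start] != -1:
            continue
        stack = [start]
        comp[start] = cid
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(adj[u] & core):
                if comp[v] == -1:
                    comp[v] = cid
                    stack.append(v)
        cid += 1
    partition = frozenset(
        frozenset(np.flatnonzero(core & (comp == c)).tolist()) for c in range(cid)
    )
    near_core = (adj & core[None, :]).any(axis=1)
    border = ~core & near_core
    noise = ~core & ~border
    return core, partition, border, noise


def union_find_components(points: np.ndarray, eps: float) -> int:
    """Number of connected components of the eps-neighborhood graph."""
    n = len(points)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d = distance_matrix(points)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= eps:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    return len({find(i) for i in range(n)})


def ray_casting_contains(polygon: np.ndarray, x: float, y: float) -> bool:
    """Crossing-number point-in-polygon test (open boundary)."""
    inside = False
    k = len(polygon)
    for i in range(k):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % k]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


def all_pairs_near_fraction(query: np.ndarray, target: np.ndarray, d: float) -> float:
    """Fraction of query points whose nearest target is within d (all-pairs)."""
    if len(query) == 0 or len(target) == 0:
        return 0.0
    hits = 0
    for q in query:
        dist = np.sqrt(((target - q) ** 2).sum(axis=1))
        if dist.min() <= d:
            hits += 1
    return hits / len(query)


def overlap_match_fraction(truth: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of planted clusters matched via the full contingency matrix.

    A planted cluster matches when >50% of its members share one detected
    non-noise label.
    """
    planted = np.unique(truth[truth >= 0])
    if len(planted) == 0:
        return 1.0
    detected = np.unique(labels[labels >= 0])
    matched = 0
    for p in planted:
        size = int((truth == p).sum())
        best = 0
        for q in detected:
            best = max(best, int(((truth == p) & (labels == q)).sum()))
        if best > 0.5 * size:
            matched += 1
    return matched / len(planted)
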