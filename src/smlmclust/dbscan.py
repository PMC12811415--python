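"""From-scratch density-based spatial clustering (core/border/noise).

The clustering radius ``eps`` is the maximum center-to-center distance at
which two localizations count as spatial neighbors (boundary inclusive);
``mnm`` is the minimum number of molecules inside that radius — query point
included — required for a core point. Cluster ids are dense integers
assigned in order of discovery over the input order; noise is -1. A border
point reachable from several clusters goes to the first cluster whose
expansion reaches it (deterministic for a fixed input order).

Neighbor search uses a uniform grid with cell size ``eps`` (9-cell stencil);
the test suite holds it to an O(n) brute-force distance scan.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from enum import Enum

import numpy as np

from smlmclust.errors import ArgumentError

NOISE = -1


class Role(str, Enum):
    CORE = "core"
    BORDER = "border"
    NOISE = "noise"


@dataclass(frozen=True)
class ClusterParams:
    """eps in nm (>0); mnm = minimum number of molecules (>=1, self included)."""

    eps: float
    mnm: int

    def __post_init__(self):
        if not self.eps > 0:
            raise ArgumentError("eps must be > 0")
        if self.mnm < 1:
            raise ArgumentError("mnm must be >= 1")


class GridIndex:
    """Fixed-radius neighbor index: uniform buckets of side eps."""

    def __init__(self, points: np.ndarray, eps: float):
        if not eps > 0:
            raise ArgumentError("eps must be > 0")
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or (len(points) and points.shape[1] != 2):
            raise ArgumentError("points must be an (n, 2) array")
        if len(points) and not np.isfinite(points).all():
            raise ArgumentError("points must be finite (no NaN/inf)")
        self.points = points
        self.eps = float(eps)
        self._cells: dict[tuple[int, int], list[int]] = {}
        keys = np.floor(points / eps).astype(np.int64) if len(points) else None
        for i in range(len(points)):
            self._cells.setdefault((keys[i, 0], keys[i, 1]), []).append(i)

    def query(self, i: int) -> np.ndarray:
        """Sorted indices of all points within eps of point i (i included)."""
        cx, cy = np.floor(self.points[i] / self.eps).astype(np.int64)
        candidates: list[int] = []
        for gx in (cx - 1, cx, cx + 1):
            for gy in (cy - 1, cy, cy + 1):
                bucket = self._cells.get((gx, gy))
                if bucket:
                    candidates.extend(bucket)
        cand = np.array(candidates, dtype=np.int64)
        d2 = np.sum((self.points[cand] - self.points[i]) ** 2, axis=1)
        hits = cand[d2 <= self.eps * self.eps]
        hits.sort()
        return hits

    def neighbor_lists(self) -> list[np.ndarray]:
        return [self.query(i) for i in range(len(self.points))]


@dataclass
class ClusterLabeling:
    """Per-localization cluster id (-1 = noise) and role assignment."""

    labels: np.ndarray
    roles: np.ndarray  # array of Role values (object dtype)
    params: ClusterParams
    n_clusters: int

    def __len__(self) -> int:
        return len(self.labels)

    def cluster_members(self, cid: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cid)

    def to_frame(self, x=None, y=None):
        import pandas as pd

        data = {"index": np.arange(len(self.labels))}
        if x is not None:
            data["x [nm]"] = np.asarray(x)
        if y is not None:
            data["y [nm]"] = np.asarray(y)
        data["cluster"] = self.labels
        data["role"] = [r.value for r in self.roles]
        return pd.DataFrame(data)


def region_query(points: np.ndarray, index: GridIndex | None, center: int, eps: float) -> np.ndarray:
    """Indices of points at Euclidean distance <= eps of ``points[center]``.

    ``center`` itself is always included. Builds a :class:`GridIndex` on the
    fly when ``index`` is None.
    """
    if index is None:
        index = GridIndex(np.asarray(points, dtype=float), eps)
    return index.query(center)


def dbscan(
    points: np.ndarray,
    params: ClusterParams,
    neighbor_lists: list[np.ndarray] | None = None,
) -> ClusterLabeling:
    """Cluster 2D points with the classic expansion algorithm.

    Parameters
    ----------
    points : (n, 2) array
        Coordinates in nm.
    params : ClusterParams
    neighbor_lists : list of ndarray, optional
        Precomputed eps-neighborhoods (self included), e.g. from
        ``GridIndex.neighbor_lists()``; allows reuse across mnm values.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2) if np.size(points) else np.empty((0, 2))
    n = len(points)
    if n and not np.isfinite(points).all():
        raise ArgumentError("points contain NaN or inf")
    labels = np.full(n, NOISE, dtype=np.int64)
    roles = np.array([Role.NOISE] * n, dtype=object)
    if n == 0:
        return ClusterLabeling(labels=labels, roles=roles, params=params, n_clusters=0)

    if neighbor_lists is None:
        neighbor_lists = GridIndex(points, params.eps).neighbor_lists()
    mnm = params.mnm
    visited = np.zeros(n, dtype=bool)
    cid = 0
    for i in range(n):
        if visited[i]:
            continue
        visited[i] = True
        neigh = neighbor_lists[i]
        if len(neigh) < mnm:
            continue  # stays noise unless a later expansion claims it as border
        labels[i] = cid
        roles[i] = Role.CORE
        seeds = deque(int(j) for j in neigh if j != i)
        while seeds:
            j = seeds.popleft()
            if labels[j] == NOISE:
                labels[j] = cid
                roles[j] = Role.BORDER
            if visited[j]:
                continue
            visited[j] = True
            jn = neighbor_lists[j]
            if len(jn) >= mnm:
                roles[j] = Role.CORE
                seeds.extend(int(k) for k in jn if labels[k] == NOISE or not visited[k])
        cid += 1
    return ClusterLabeling(labels=labels, roles=roles, params=params, n_clusters=cid)


def eps_disc_area(eps: float) -> float:
    """Area of the eps-neighborhood disc in square microns."""
    if eps < 0:
        raise ArgumentError("eps must be >= 0")
    return np.pi * eps * eps * 1e-6  # nm^2 -> um^2


def local_density(count: int, eps: float) -> float:
    """Molecules per square micron inside one eps disc."""
    if count < 0:
        raise ArgumentError("count must be >= 0")
    if not eps > 0:
        raise ArgumentError("eps must be > 0")
    return count / eps_disc_area(eps)
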