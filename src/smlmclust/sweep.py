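"""Cluster-count profiles over a grid of MNM values at fixed eps.

The central statistic: the number of detected clusters as a function of the
minimum number of molecules (MNM) at a fixed epsilon radius, normalized per
ROI and aggregated over many ROIs/cells. The default grid spans 10..1200
(step 10 up to 100, step 50 above).

Implementation note: at fixed eps the neighborhood graph is fixed, and the
clusters of a density-based run biject with the connected components of the
subgraph induced by core points (points with >= mnm neighbors, self
included). The sweep therefore builds the eps graph once and counts
components per mnm with scipy.sparse.csgraph; equivalence with the full
expansion algorithm is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from smlmclust.dbscan import GridIndex
from smlmclust.errors import ArgumentError
from smlmclust.io import LocalizationTable


def default_mnm_grid() -> np.ndarray:
    """10..100 step 10, then 150..1200 step 50."""
    return np.concatenate([np.arange(10, 101, 10), np.arange(150, 1201, 50)])


@dataclass
class SweepProfile:
    eps: float
    mnm_grid: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray
    roi_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.mnm_grid = np.asarray(self.mnm_grid, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if not (len(self.mnm_grid) == len(self.counts) == len(self.normalized)):
            raise ArgumentError("grid/count/normalized lengths differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi_id": self.roi_id,
                "condition": self.condition,
                "eps": self.eps,
                "mnm": self.mnm_grid,
                "count": self.counts,
                "normalized": self.normalized,
            }
        )


@dataclass
class AggregateProfile:
    mnm_grid: np.ndarray
    mean_normalized: np.ndarray
    dispersion: np.ndarray  # population std per grid value
    n_rois: int
    condition: str = ""
    eps: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition": self.condition,
                "eps": self.eps,
                "mnm": self.mnm_grid,
                "mean_normalized": self.mean_normalized,
                "dispersion": self.dispersion,
                "n_rois": self.n_rois,
            }
        )

    def modal_mnm(self) -> int:
        """Grid value maximizing the mean normalized count (ties -> smallest)."""
        return int(self.mnm_grid[int(np.argmax(self.mean_normalized))])


@dataclass
class ConditionComparison:
    mnm_grid: np.ndarray
    mean_difference: np.ndarray  # a - b per grid value
    modal_mnm_a: int
    modal_mnm_b: int
    summary_distance: float  # L-infinity between mean normalized profiles


def _validate_grid(mnm_grid: np.ndarray):
    if len(mnm_grid) == 0:
        raise ArgumentError("mnm grid must be non-empty")
    if (mnm_grid < 1).any():
        raise ArgumentError("mnm values must be >= 1")
    if (np.diff(mnm_grid) <= 0).any():
        raise ArgumentError("mnm grid must be strictly ascending")


def cluster_counts_over_grid(points: np.ndarray, eps: float, mnm_grid: np.ndarray) -> np.ndarray:
    """Number of detected clusters at each mnm, sharing one eps graph."""
    n = len(points)
    if n == 0:
        return np.zeros(len(mnm_grid), dtype=np.int64)
    neighbors = GridIndex(np.asarray(points, dtype=float), eps).neighbor_lists()
    degree = np.array([len(nb) for nb in neighbors])  # self included
    rows = np.repeat(np.arange(n), degree)
    cols = np.concatenate(neighbors)
    adj = sp.csr_matrix((np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n))
    counts = np.zeros(len(mnm_grid), dtype=np.int64)
    for k, mnm in enumerate(mnm_grid):
        core = degree >= mnm
        if not core.any():
            continue
        sub = adj[core][:, core]
        counts[k], _ = connected_components(sub, directed=False)
    return counts


def sweep(
    table: LocalizationTable,
    eps: float,
    mnm_grid: np.ndarray | None = None,
    roi_id: str = "",
    condition: str = "",
    normalization: str = "max",
) -> SweepProfile:
    """Profile of cluster counts over the mnm grid at fixed eps."""
    if not eps > 0:
        raise ArgumentError("eps must be > 0")
    grid = default_mnm_grid() if mnm_grid is None else np.asarray(mnm_grid, dtype=np.int64)
    _validate_grid(grid)
    counts = cluster_counts_over_grid(table.coords(), eps, grid)
    return SweepProfile(
        eps=eps,
        mnm_grid=grid,
        counts=counts,
        normalized=normalize_profile(counts, mode=normalization),
        roi_id=roi_id,
        condition=condition,
    )


def normalize_profile(counts, mode: str = "max") -> np.ndarray:
    """Scale counts so the peak is 1 (``max``) or the sum is 1 (``sum``).

    All-zero input maps to all zeros.
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ArgumentError("counts must be non-negative")
    if mode == "max":
        denom = counts.max() if len(counts) else 0.0
    elif mode == "sum":
        denom = counts.sum()
    else:
        raise ArgumentError(f"unknown normalization mode {mode!r}")
    if denom <= 0:
        return np.zeros_like(counts)
    return counts / denom


def aggregate(profiles: list[SweepProfile]) -> AggregateProfile:
    """Per-grid mean and population std of normalized counts."""
    if not profiles:
        raise ArgumentError("need at least one profile")
    grid = profiles[0].mnm_grid
    for p in profiles[1:]:
        if len(p.mnm_grid) != len(grid) or (p.mnm_grid != grid).any():
            raise ArgumentError("profiles have mismatched mnm grids")
    stack = np.vstack([p.normalized for p in profiles])
    return AggregateProfile(
        mnm_grid=grid.copy(),
        mean_normalized=stack.mean(axis=0),
        dispersion=stack.std(axis=0, ddof=0),
        n_rois=len(profiles),
        condition=profiles[0].condition,
        eps=profiles[0].eps,
    )


def compare_conditions(a: AggregateProfile, b: AggregateProfile) -> ConditionComparison:
    """Per-grid mean differences, modal MNM per condition, L-inf distance."""
    if len(a.mnm_grid) != len(b.mnm_grid) or (a.mnm_grid != b.mnm_grid).any():
        raise ArgumentError("aggregate profiles have mismatched mnm grids")
    diff = a.mean_normalized - b.mean_normalized
    return ConditionComparison(
        mnm_grid=a.mnm_grid.copy(),
        mean_difference=diff,
        modal_mnm_a=a.modal_mnm(),
        modal_mnm_b=b.modal_mnm(),
        summary_distance=float(np.max(np.abs(diff))) if len(diff) else 0.0,
    )
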