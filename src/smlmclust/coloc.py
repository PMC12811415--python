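"""Two-channel colocalization at localization and cluster level.

A localization in one channel is "near" the other channel when its nearest
cross-channel neighbor lies within the distance threshold (default 75 nm,
the channel-A clustering radius). Cluster-level colocalization compares
cluster centroids (noise excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from smlmclust.dbscan import ClusterLabeling
from smlmclust.errors import ArgumentError
from smlmclust.io import LocalizationTable

DEFAULT_COLOC_DISTANCE_NM = 75.0


@dataclass(frozen=True)
class ColocalizationResult:
    distance_threshold: float
    frac_A_near_B: float
    frac_B_near_A: float
    n_A: int
    n_B: int


def coloc_fraction(
    a: LocalizationTable, b: LocalizationTable, d: float = DEFAULT_COLOC_DISTANCE_NM
) -> ColocalizationResult:
    """Fraction of each channel's localizations within d of the other channel.

    An empty channel yields a fraction of 0 for its direction, with the
    zero count carried in the result.
    """
    if not d > 0:
        raise ArgumentError("distance threshold must be > 0")
    n_a, n_b = len(a), len(b)
    frac_ab = _near_fraction(a.coords(), b.coords(), d)
    frac_ba = _near_fraction(b.coords(), a.coords(), d)
    return ColocalizationResult(
        distance_threshold=d, frac_A_near_B=frac_ab, frac_B_near_A=frac_ba, n_A=n_a, n_B=n_b
    )


def _near_fraction(query: np.ndarray, target: np.ndarray, d: float) -> float:
    if len(query) == 0 or len(target) == 0:
        return 0.0
    dist, _ = cKDTree(target).query(query, k=1, distance_upper_bound=d * (1 + 1e-12))
    return float(np.mean(dist <= d))


def cluster_centroids(table: LocalizationTable, labeling: ClusterLabeling) -> np.ndarray:
    """(k, 2) arithmetic-mean centroid per cluster id 0..k-1; noise excluded."""
    coords = table.coords()
    out = np.empty((labeling.n_clusters, 2))
    for cid in range(labeling.n_clusters):
        out[cid] = coords[labeling.labels == cid].mean(axis=0)
    return out


def cluster_coloc(
    table_a: LocalizationTable,
    labels_a: ClusterLabeling,
    table_b: LocalizationTable,
    labels_b: ClusterLabeling,
    d: float = DEFAULT_COLOC_DISTANCE_NM,
) -> pd.DataFrame:
    """Per-channel-A-cluster nearest channel-B centroid distance and flag.

    Returns an empty frame when channel A has no clusters. When channel B
    has no clusters the distance is +inf and every flag is False.
    """
    if not d > 0:
        raise ArgumentError("distance threshold must be > 0")
    columns = ["cluster_a", "centroid_x", "centroid_y", "nearest_b", "distance", "colocalized"]
    if labels_a.n_clusters == 0:
        return pd.DataFrame(columns=columns)
    cent_a = cluster_centroids(table_a, labels_a)
    if labels_b.n_clusters == 0:
        return pd.DataFrame(
            {
                "cluster_a": np.arange(labels_a.n_clusters),
                "centroid_x": cent_a[:, 0],
                "centroid_y": cent_a[:, 1],
                "nearest_b": -1,
                "distance": np.inf,
                "colocalized": False,
            }
        )
    cent_b = cluster_centroids(table_b, labels_b)
    dist, nearest = cKDTree(cent_b).query(cent_a, k=1)
    return pd.DataFrame(
        {
            "cluster_a": np.arange(labels_a.n_clusters),
            "centroid_x": cent_a[:, 0],
            "centroid_y": cent_a[:, 1],
            "nearest_b": nearest,
            "distance": dist,
            "colocalized": dist <= d,
        }
    )
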