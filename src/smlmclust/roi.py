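"""Polygonal regions of interest: categories, clipping, summaries.

ROIs are authored in a sidecar JSON file rather than interactively, so an
analysis is reproducible from text inputs alone. Boundary points count as
inside; when ROIs overlap, a localization belongs to the ROI listed first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon

from smlmclust.errors import ArgumentError, FormatError, IOFailure
from smlmclust.io import LocalizationTable

CATEGORIES = ("single_cell", "multiple_cells", "particle", "particle_with_cells")


@dataclass
class RegionOfInterest:
    """Simple polygon (vertices in nm) with a category label and id."""

    vertices: np.ndarray  # (k, 2), k >= 3
    category: str
    id: str

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[0] < 3 or self.vertices.shape[1] != 2:
            raise ArgumentError("an ROI needs >= 3 (x, y) vertices")
        if self.category not in CATEGORIES:
            raise ArgumentError(f"unknown ROI category {self.category!r}; expected one of {CATEGORIES}")
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ArgumentError(f"ROI {self.id!r}: polygon must be simple with positive area")
        self._polygon = poly

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def area_um2(self) -> float:
        """Polygon area in square microns (shoelace formula)."""
        return self._polygon.area * 1e-6

    def contains(self, x, y) -> np.ndarray:
        """Vectorized inside-or-on-boundary test."""
        pts = shapely.points(np.asarray(x, dtype=float), np.asarray(y, dtype=float))
        return shapely.covers(self._polygon, pts)


def clip_to_roi(table: LocalizationTable, roi: RegionOfInterest) -> LocalizationTable:
    """Localizations inside or on the ROI boundary, order preserved."""
    if len(table) == 0:
        return table.take(np.empty(0, dtype=np.int64))
    keep = np.flatnonzero(roi.contains(table.x, table.y))
    return table.take(keep)


def assign_rois(table: LocalizationTable, rois: list[RegionOfInterest]) -> np.ndarray:
    """Index of the first ROI covering each localization (-1 = none).

    The first-listed-ROI rule makes partitions conserve counts even when
    ROIs share edges.
    """
    out = np.full(len(table), -1, dtype=np.int64)
    for k, roi in enumerate(rois):
        unassigned = out == -1
        if not unassigned.any():
            break
        hit = roi.contains(table.x[unassigned], table.y[unassigned])
        idx = np.flatnonzero(unassigned)[hit]
        out[idx] = k
    return out


def roi_summary(table: LocalizationTable, roi: RegionOfInterest) -> tuple[int, float, float]:
    """(localization count, ROI area in um^2, density per um^2)."""
    area = roi.area_um2()
    if area <= 0:
        raise ArgumentError("zero-area polygon")
    count = len(clip_to_roi(table, roi))
    return count, area, count / area


def read_rois(path) -> list[RegionOfInterest]:
    """Read the ROI sidecar: JSON list of {id, category, vertices}."""
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid ROI sidecar {path}: {exc}") from exc
    if not isinstance(raw, list):
        raise FormatError("ROI sidecar must be a JSON list")
    rois = []
    for item in raw:
        for key in ("id", "category", "vertices"):
            if key not in item:
                raise FormatError(f"ROI entry missing key {key!r}")
        rois.append(
            RegionOfInterest(vertices=np.asarray(item["vertices"], dtype=float), category=item["category"], id=str(item["id"]))
        )
    return rois


def write_rois(rois: list[RegionOfInterest], path):
    payload = [
        {"id": r.id, "category": r.category, "vertices": np.asarray(r.vertices, dtype=float).tolist()}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
    return Path(path)
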