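"""Localization-table I/O in a ThunderSTORM-style delimited-text dialect.

Coordinates are stored in nanometres throughout the pipeline; pixel units
exist only at this boundary (:func:`pixels_to_length`). The coordinate
convention is the standard image one: origin top-left, y increasing
downward, 0-based continuous nm positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from smlmclust.errors import (
    ArgumentError,
    EmptyTableError,
    FormatError,
    IOFailure,
    RowParseError,
)


class Channel(str, Enum):
    """Imaging channel: A = Alexa Fluor 647 anti-CBM3a, B = PA-GFP dockerin."""

    A_AF647 = "A_af647"
    B_PAGFP = "B_pagfp"


#: Default clustering radius (nm) per channel.
DEFAULT_EPS_NM: dict[Channel, float] = {Channel.A_AF647: 75.0, Channel.B_PAGFP: 125.0}

# ThunderSTORM-style header names.
_COL_X = "x [nm]"
_COL_Y = "y [nm]"
_COL_FRAME = "frame"
_COL_UNC = "uncertainty [nm]"
_REQUIRED_COLUMNS = (_COL_X, _COL_Y, _COL_FRAME, _COL_UNC)


@dataclass(frozen=True)
class Localization:
    """A single detected emission event."""

    x: float
    y: float
    frame: int
    uncertainty: float
    channel: Channel

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ArgumentError("coordinates must be finite")
        if self.x < 0 or self.y < 0:
            raise ArgumentError("coordinates must be >= 0 (origin top-left)")
        if self.frame < 1 or int(self.frame) != self.frame:
            raise ArgumentError("frame must be a positive integer")
        if not self.uncertainty > 0:
            raise ArgumentError("uncertainty must be > 0")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Camera geometry of an acquisition."""

    pixel_size: float = 100.0  # nm per pixel
    field_pixels: tuple[int, int] = (256, 256)
    n_frames: int = 15000

    def __post_init__(self):
        if not self.pixel_size > 0:
            raise ArgumentError("pixel_size must be > 0")
        if any(p <= 0 for p in self.field_pixels):
            raise ArgumentError("field_pixels components must be > 0")
        if self.n_frames <= 0:
            raise ArgumentError("n_frames must be > 0")

    @property
    def field_extent(self) -> tuple[float, float]:
        """Physical field size (width nm, height nm)."""
        return (
            pixels_to_length(self.field_pixels[0], self),
            pixels_to_length(self.field_pixels[1], self),
        )


@dataclass
class LocalizationTable:
    """Columnar localization data for one channel.

    Parameters
    ----------
    x, y : ndarray of float
        Coordinates in nm (origin top-left, y downward).
    frame : ndarray of int
        1-based acquisition frame indices.
    uncertainty : ndarray of float
        Per-localization precision in nm, strictly positive.
    channel : Channel
    field_extent : (float, float), optional
        Width and height of the field in nm. Inferred as the coordinate
        bounding box when omitted.
    provenance : str
        Free-text source tag.
    """

    x: np.ndarray
    y: np.ndarray
    frame: np.ndarray
    uncertainty: np.ndarray
    channel: Channel
    field_extent: tuple[float, float] | None = None
    provenance: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        n = len(self.x)
        if not (len(self.y) == len(self.frame) == len(self.uncertainty) == n):
            raise ArgumentError("column lengths differ")
        if n:
            if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
                raise ArgumentError("coordinates must be finite")
            if (self.x < 0).any() or (self.y < 0).any():
                raise ArgumentError("coordinates must be >= 0")
            if (self.frame < 1).any():
                raise ArgumentError("frames must be >= 1")
            if (self.uncertainty <= 0).any():
                raise ArgumentError("uncertainties must be > 0")
        if self.field_extent is None:
            if n:
                self.field_extent = (float(self.x.max()), float(self.y.max()))
            else:
                self.field_extent = (0.0, 0.0)
        else:
            w, h = self.field_extent
            if n and ((self.x > w).any() or (self.y > h).any()):
                raise ArgumentError("coordinates exceed field_extent")

    def __len__(self) -> int:
        return len(self.x)

    def __iter__(self) -> Iterator[Localization]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> Localization:
        return Localization(
            x=float(self.x[i]),
            y=float(self.y[i]),
            frame=int(self.frame[i]),
            uncertainty=float(self.uncertainty[i]),
            channel=self.channel,
        )

    def coords(self) -> np.ndarray:
        """(n, 2) array of x-y coordinates in nm."""
        return np.column_stack([self.x, self.y])

    def take(self, indices) -> "LocalizationTable":
        """Sub-table at the given row indices, order as given."""
        idx = np.asarray(indices)
        return replace(
            self,
            x=self.x[idx],
            y=self.y[idx],
            frame=self.frame[idx],
            uncertainty=self.uncertainty[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                _COL_X: self.x,
                _COL_Y: self.y,
                _COL_FRAME: self.frame,
                _COL_UNC: self.uncertainty,
            }
        )

    @classmethod
    def empty(cls, channel: Channel, field_extent=None) -> "LocalizationTable":
        return cls(
            x=np.empty(0),
            y=np.empty(0),
            frame=np.empty(0, dtype=np.int64),
            uncertainty=np.empty(0),
            channel=channel,
            field_extent=field_extent,
        )


def read_localizations(
    path,
    channel: Channel,
    dialect: str = "thunderstorm_csv",
    field_extent: tuple[float, float] | None = None,
) -> LocalizationTable:
    """Read a delimited localization table.

    The header must name at least ``x [nm]``, ``y [nm]``, ``frame`` and
    ``uncertainty [nm]``; extra columns are ignored. Rows are returned in
    file order.

    Raises
    ------
    FormatError
        Missing required column, or unknown dialect.
    RowParseError
        A non-numeric value in a data row (carries the 1-based line number).
    EmptyTableError
        The file is completely empty.
    """
    _check_dialect(dialect)
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise EmptyTableError(f"empty file: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip().strip('"') for c in df.columns]
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {path}")
    cols = {}
    for col in _REQUIRED_COLUMNS:
        raw = df[col].str.strip('"')
        numeric = pd.to_numeric(raw, errors="coerce")
        bad = numeric.isna() & raw.notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            # +2: 1-based plus the header line
            raise RowParseError(
                f"non-numeric value {raw.iloc[row]!r} in column {col!r} "
                f"at line {row + 2} of {path}",
                line=row + 2,
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise RowParseError(f"missing value in column {col!r} at line {row + 2}", line=row + 2)
        cols[col] = numeric.to_numpy()
    return LocalizationTable(
        x=cols[_COL_X],
        y=cols[_COL_Y],
        frame=cols[_COL_FRAME].astype(np.int64),
        uncertainty=cols[_COL_UNC],
        channel=channel,
        field_extent=field_extent,
        provenance=str(path),
    )


def write_localizations(table: LocalizationTable, path, dialect: str = "thunderstorm_csv"):
    """Write a table so that :func:`read_localizations` round-trips it."""
    _check_dialect(dialect)
    path = Path(path)
    try:
        table.to_frame().to_csv(path, index=False, float_format="%.4f")
    except OSError as exc:
        raise IOFailure(f"cannot write {path}: {exc}") from exc
    return path


def filter_by_uncertainty(table: LocalizationTable, max_uncertainty: float) -> LocalizationTable:
    """Keep exactly the localizations with uncertainty <= threshold (inclusive)."""
    if not max_uncertainty > 0:
        raise ArgumentError("max_uncertainty must be > 0")
    keep = np.flatnonzero(table.uncertainty <= max_uncertainty)
    return table.take(keep)


def pixels_to_length(n_pixels: int, geometry: AcquisitionGeometry) -> float:
    """Convert a pixel count to a physical length in nm."""
    if n_pixels < 0:
        raise ArgumentError("n_pixels must be >= 0")
    return n_pixels * geometry.pixel_size


def _check_dialect(dialect: str):
    if dialect != "thunderstorm_csv":
        raise FormatError(f"unknown dialect {dialect!r}")
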