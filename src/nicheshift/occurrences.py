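"""Occurrence records: CSV I/O, coordinate validation and one-per-grid-cell thinning.

The CSV dialect is the MaxEnt "samples" format: ``species,longitude,latitude``
(longitude first). Thinning keeps, within each occupied grid cell, the record
closest to the cell center — the standard de-clustering step for
presence-background modelling, which otherwise double-counts survey effort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = ["OccurrenceSet", "read_occurrences", "thin_to_grid", "write_samples_csv"]

_COLUMNS = ["species", "longitude", "latitude"]


@dataclass
class OccurrenceSet:
    """Ordered presence records in geographic WGS84 coordinates."""

    records: pd.DataFrame  # columns species, longitude, latitude [, source]
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def lon(self) -> np.ndarray:
        return self.records["longitude"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.records["latitude"].to_numpy(dtype=float)

    @classmethod
    def from_arrays(cls, species: str, lon, lat, source: str | None = None) -> "OccurrenceSet":
        df = pd.DataFrame(
            {"species": species, "longitude": np.asarray(lon, float), "latitude": np.asarray(lat, float)}
        )
        if source is not None:
            df["source"] = source
        return cls(records=df)


def read_occurrences(path: str | Path) -> OccurrenceSet:
    """Read a samples CSV, dropping rows with unparseable or out-of-range coordinates.

    Requires columns ``species``, ``longitude``, ``latitude``. Dropped rows are
    counted in a log warning, never silently discarded.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no occurrence rows")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    n_raw = len(df)
    for col in ("longitude", "latitude"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df["longitude"].between(-180, 180)
        & df["latitude"].between(-90, 90)
        & df["longitude"].notna()
        & df["latitude"].notna()
    )
    if (~ok).any():
        logger.warning("%s: dropped %d rows with invalid coordinates", path, int((~ok).sum()))
    df = df[ok].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no valid occurrence rows after coordinate checks")
    return OccurrenceSet(records=df)


def thin_to_grid(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Retain one record per occupied grid cell: the one nearest the cell center.

    Distances are Euclidean in degrees (within a single cell the lon/lat
    anisotropy is immaterial). Ties are broken by the lexicographically
    smallest (longitude, latitude, source) tuple so the result is independent
    of input order. Records falling outside the grid are dropped with a
    warning; the output count equals the number of occupied cells.
    """
    if len(occ) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    df = occ.records.copy()
    row, col = grid.cell_of(occ.lon, occ.lat)
    inside = (row >= 0) & (col >= 0)
    if (~inside).any():
        logger.warning("thin_to_grid: dropped %d records outside the grid", int((~inside).sum()))
    df = df[inside].reset_index(drop=True)
    if df.empty:
        raise ValueError("no records fall on the grid")
    row, col = row[inside], col[inside]
    clon, clat = grid.cell_center(row, col)
    df["_cell"] = row * grid.n_cols + col
    df["_d2"] = (df["longitude"].to_numpy() - clon) ** 2 + (df["latitude"].to_numpy() - clat) ** 2
    sort_cols = ["_cell", "_d2", "longitude", "latitude"]
    if "source" in df.columns:
        sort_cols.append("source")
    df = df.sort_values(sort_cols, kind="mergesort")
    kept = df.drop_duplicates("_cell", keep="first").sort_values("_cell")
    kept = kept.drop(columns=["_cell", "_d2"]).reset_index(drop=True)
    logger.info("thin_to_grid: %d -> %d records after thinning", len(occ), len(kept))
    return OccurrenceSet(records=kept)


def write_samples_csv(occ: OccurrenceSet, path: str | Path) -> Path:
    """Write ``species,longitude,latitude`` CSV; round-trips through read_occurrences."""
    if len(occ) == 0:
        raise ValueError("refusing to write an empty occurrence set")
    path = Path(path)
    occ.records[_COLUMNS].to_csv(path, index=False, float_format="%.6f")
    return path
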