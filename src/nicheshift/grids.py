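"""Geographic grids, raster stacks and ESRI ASCII grid I/O.

All rasters in this package live on a regular lon/lat grid (WGS84 degrees)
described by a :class:`GridSpec`. Arrays are stored row-major with row 0 at
the *northern* edge, matching the ESRI ASCII grid convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_NODATA = -9999.0

__all__ = [
    "GridSpec",
    "EnvStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "DEFAULT_NODATA",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid; ``origin_lon``/``origin_lat`` is the upper-left corner."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin_lon: float
    origin_lat: float
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        east = self.origin_lon + self.n_cols * self.cell_size
        south = self.origin_lat - self.n_rows * self.cell_size
        if not (-180.0 <= self.origin_lon and east <= 180.0 + 1e-9):
            raise ValueError("grid longitudes outside [-180, 180]")
        if not (-90.0 - 1e-9 <= south and self.origin_lat <= 90.0 + 1e-9):
            raise ValueError("grid latitudes outside [-90, 90]")

    @property
    def xllcorner(self) -> float:
        return self.origin_lon

    @property
    def yllcorner(self) -> float:
        return self.origin_lat - self.n_rows * self.cell_size

    @property
    def lon_centers(self) -> np.ndarray:
        """Cell-center longitudes, west to east (length n_cols)."""
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (length n_rows)."""
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def cell_of(self, lon, lat):
        """Map coordinates to (row, col) indices.

        Cells are half-open ``[west, east) x [south, north)``: a point on a
        shared edge belongs to the cell to its east/north. Points off the grid
        get index -1 in the offending dimension.
        """
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        # snap near-integer index values (1e-9 cells ~ sub-micron) so points on
        # a shared edge land in the east/north cell despite float rounding
        u = (lon - self.origin_lon) / self.cell_size
        v = (lat - self.yllcorner) / self.cell_size
        col = np.floor(np.where(np.abs(u - np.rint(u)) < 1e-9, np.rint(u), u)).astype(int)
        row_s = np.floor(np.where(np.abs(v - np.rint(v)) < 1e-9, np.rint(v), v)).astype(int)
        row = self.n_rows - 1 - row_s
        col = np.where((col >= 0) & (col < self.n_cols), col, -1)
        row = np.where((row >= 0) & (row < self.n_rows), row, -1)
        return row, col

    def cell_center(self, row, col):
        """(lon, lat) of the center of cell (row, col)."""
        lon = self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size
        lat = self.origin_lat - (np.asarray(row) + 0.5) * self.cell_size
        return lon, lat


@dataclass
class EnvStack:
    """Named, co-registered environmental layers sharing one grid and mask."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name, arr in self.layers.items():
            if arr.shape != shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {shape}")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        elif self.mask.shape != shape:
            raise ValueError("mask shape does not match grid")

    @property
    def layer_names(self) -> list[str]:
        return list(self.layers)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def valid_rc(self) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of valid (unmasked) cells, row-major order."""
        return np.nonzero(self.mask)

    def extract(self, lon, lat, names: list[str] | None = None) -> np.ndarray:
        """Sample layer values at point coordinates -> array (n_points, n_layers).

        Points off the grid or on masked cells yield NaN rows.
        """
        names = names or self.layer_names
        row, col = self.grid.cell_of(lon, lat)
        ok = (row >= 0) & (col >= 0)
        ok &= self.mask[np.where(ok, row, 0), np.where(ok, col, 0)]
        out = np.full((np.size(row), len(names)), np.nan)
        r, c = row[ok], col[ok]
        for j, name in enumerate(names):
            out[ok, j] = self.layers[name][r, c]
        return out

    def to_matrix(self, names: list[str] | None = None) -> np.ndarray:
        """Valid-cell values as (n_valid, n_layers), row-major cell order."""
        names = names or self.layer_names
        r, c = self.valid_rc()
        return np.column_stack([self.layers[n][r, c] for n in names])

    def write_dir(self, directory: str | Path) -> list[Path]:
        """Write one ``<name>.asc`` per layer; returns the paths written."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, arr in self.layers.items():
            data = np.where(self.mask, arr, self.grid.nodata_value)
            p = directory / f"{name}.asc"
            write_ascii_grid(p, self.grid, data)
            paths.append(p)
        return paths

    @classmethod
    def read_dir(cls, directory: str | Path) -> "EnvStack":
        """Read every ``*.asc`` in a directory (sorted by name) into one stack."""
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers in {directory}")
        layers: dict[str, np.ndarray] = {}
        grid = None
        mask = None
        for p in paths:
            g, arr = read_ascii_grid(p)
            if grid is None:
                grid = g
                mask = arr != g.nodata_value
            elif (g.n_rows, g.n_cols, g.cell_size) != (grid.n_rows, grid.n_cols, grid.cell_size) or not (
                math.isclose(g.origin_lon, grid.origin_lon) and math.isclose(g.origin_lat, grid.origin_lat)
            ):
                raise ValueError(f"layer {p.name} is not co-registered with the stack")
            layers[p.stem] = arr
        return cls(grid=grid, layers=layers, mask=mask)


def write_ascii_grid(path: str | Path, grid: GridSpec, data: np.ndarray) -> None:
    """Write an ESRI ASCII grid (.asc)."""
    data = np.asarray(data)
    if data.shape != (grid.n_rows, grid.n_cols):
        raise ValueError("data shape does not match grid")
    header = (
        f"NCOLS {grid.n_cols}\n"
        f"NROWS {grid.n_rows}\n"
        f"XLLCORNER {grid.xllcorner!r}\n"
        f"YLLCORNER {grid.yllcorner!r}\n"
        f"CELLSIZE {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata_value!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; returns (GridSpec, 2-D array)."""
    head: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            head[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(head["nrows"]), int(head["ncols"])
    cs = head["cellsize"]
    if "xllcenter" in head:  # center-referenced variant
        head["xllcorner"] = head["xllcenter"] - cs / 2
        head["yllcorner"] = head["yllcenter"] - cs / 2
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cs,
        origin_lon=head["xllcorner"],
        origin_lat=head["yllcorner"] + n_rows * cs,
        nodata_value=head.get("nodata_value", DEFAULT_NODATA),
    )
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} disagrees with header")
    return grid, data
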