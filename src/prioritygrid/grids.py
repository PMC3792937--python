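"""Rectangular lattice grids, layers, and ESRI ASCII grid I/O.

Coordinates are geographic degrees treated as planar (Euclidean). Cells are
indexed (row, col) with row 0 at the north edge. Cell (r, c) covers the
half-open box ``[origin_lon + c*s, origin_lon + (c+1)*s)`` in longitude and
``(origin_lat - (r+1)*s, origin_lat - r*s]`` in latitude, so a point on a
shared edge belongs to exactly one cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GridSpec",
    "Layer",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular grid: top-left origin, cell size, shape."""

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(
                f"grid shape must be >= 1x1, got {self.n_rows}x{self.n_cols}"
            )

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max)."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size,
            self.origin_lon + self.n_cols * self.cell_size,
            self.origin_lat,
        )

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Map a point to its (row, col) cell; raise if outside the extent."""
        s = self.cell_size
        col = math.floor((lon - self.origin_lon) / s)
        # lat axis points down: row r spans (origin_lat-(r+1)s, origin_lat-rs],
        # so r <= (origin_lat - lat)/s < r+1 and a shared horizontal edge
        # belongs to the row below it
        row = math.floor((self.origin_lat - lat) / s)
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({lon}, {lat}) outside grid extent {self.extent}")
        return (row, col)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        s = self.cell_size
        return (
            self.origin_lon + (col + 0.5) * s,
            self.origin_lat - (row + 0.5) * s,
        )

    def cell_box(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(lon_min, lat_min, lon_max, lat_max) of one cell."""
        s = self.cell_size
        x0 = self.origin_lon + col * s
        y1 = self.origin_lat - row * s
        return (x0, y1 - s, x0 + s, y1)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of cell-center lon and lat."""
        s = self.cell_size
        lon = self.origin_lon + (np.arange(self.n_cols) + 0.5) * s
        lat = self.origin_lat - (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(lon, lat)

    def iter_cells(self) -> Iterator[tuple[int, int]]:
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield (r, c)

    # -- nesting ------------------------------------------------------------

    def coarsen(self, k: int) -> "GridSpec":
        """Spec of the nested coarse grid whose cells are k x k blocks."""
        if k < 2:
            raise ValueError(f"nesting factor must be >= 2, got {k}")
        if self.n_rows % k or self.n_cols % k:
            raise ValueError(
                f"grid shape {self.shape} not divisible by nesting factor {k}"
            )
        return GridSpec(
            self.origin_lon,
            self.origin_lat,
            self.cell_size * k,
            self.n_rows // k,
            self.n_cols // k,
        )

    def nesting_factor(self, coarse: "GridSpec") -> int:
        """Integer k such that ``coarse`` is this grid coarsened by k.

        Raises ValueError if the grids are not nested (ratio not an integer
        >= 2, or origins/extents differ).
        """
        ratio = coarse.cell_size / self.cell_size
        k = round(ratio)
        if k < 2 or not math.isclose(ratio, k, rel_tol=1e-9):
            raise ValueError(
                f"cell sizes {self.cell_size} and {coarse.cell_size} are not "
                "nested by an integer factor >= 2"
            )
        if not (
            math.isclose(self.origin_lon, coarse.origin_lon, abs_tol=1e-9)
            and math.isclose(self.origin_lat, coarse.origin_lat, abs_tol=1e-9)
            and self.n_rows == coarse.n_rows * k
            and self.n_cols == coarse.n_cols * k
        ):
            raise ValueError("grid extents do not coincide; grids are not nested")
        return k

    def parent_cell(self, row: int, col: int, k: int) -> tuple[int, int]:
        return (row // k, col // k)


@dataclass
class Layer:
    """A named value field on a grid. NaN marks missing cells.

    ``categorical`` layers hold integer class codes stored as floats.
    """

    spec: GridSpec
    values: np.ndarray
    name: str = ""
    categorical: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"layer shape {self.values.shape} does not match grid "
                f"{self.spec.shape}"
            )

    def copy_with(self, values: np.ndarray, **kw) -> "Layer":
        out = Layer(self.spec, np.asarray(values, dtype=float), self.name,
                    self.categorical)
        for key, val in kw.items():
            setattr(out, key, val)
        return out


# -- ESRI ASCII grid I/O -----------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value")


def write_ascii_grid(layer: Layer, path: str | Path, nodata: float = -9999.0) -> None:
    spec = layer.spec
    lon_min, lat_min, _, _ = spec.extent
    vals = np.where(np.isnan(layer.values), nodata, layer.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {lon_min!r}\n")
        fh.write(f"yllcorner {lat_min!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path, name: str = "",
                    categorical: bool = False) -> Layer:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key not in _HEADER_KEYS:
                fh.seek(pos)
                break
            header[key] = float(value)
            pos = fh.tell()
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"missing '{key}' in ASCII grid header of {path}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    spec = GridSpec(
        origin_lon=header.get("xllcorner", 0.0),
        origin_lat=header.get("yllcorner", 0.0) + nrows * header["cellsize"],
        cell_size=header["cellsize"],
        n_rows=nrows,
        n_cols=ncols,
    )
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(data == nodata, np.nan, data)
    if not name:
        name = Path(path).stem
    return Layer(spec, data, name=name, categorical=categorical)
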