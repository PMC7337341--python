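"""Aligned environmental raster stacks on a geographic (WGS84) grid.

A :class:`ClimateStack` holds K co-registered single-band layers over one
lon/lat grid.  Grids follow the usual raster convention: row 0 is the
northernmost row, coordinates refer to cell centers, and grid intervals are
half-open in index space.  Layers are stored as a dense float array with a
shared validity mask: a cell where *any* layer is nodata is invalid in every
layer (nodata propagation), so every downstream extraction sees one
consistent domain.

Raster I/O uses the Arc/Info ASCII grid format (``.asc``) — a plain-text,
single-band format with a 6-line header — one file per variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

WGS84 = "EPSG:4326"

__all__ = [
    "GridSpec",
    "ClimateStack",
    "EnvelopeBox",
    "read_ascii_grid",
    "write_ascii_grid",
    "load_stack",
    "extract_values",
    "fit_envelope",
    "apply_envelope_mask",
]


@dataclass(frozen=True)
class GridSpec:
    """Geographic grid geometry: lower-left corner, square cells, shape."""

    nrows: int
    ncols: int
    xll: float  # longitude of the lower-left corner of the lower-left cell
    yll: float  # latitude of the lower-left corner of the lower-left cell
    cellsize: float  # degrees, square cells

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def west(self) -> float:
        return self.xll

    @property
    def east(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def south(self) -> float:
        return self.yll

    @property
    def north(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) of cell centers for (row, col) indices (row 0 = north)."""
        lon = self.xll + (np.asarray(col) + 0.5) * self.cellsize
        lat = self.north - (np.asarray(row) + 0.5) * self.cellsize
        return lon, lat

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Grid indices containing the given points; -1 where out of extent."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.xll) / self.cellsize).astype(int)
        row = np.floor((self.north - lat) / self.cellsize).astype(int)
        # points exactly on the north/east edge belong to the last cell
        col = np.where((lon == self.east), self.ncols - 1, col)
        row = np.where((lat == self.south) & (row == self.nrows), self.nrows - 1, row)
        bad = (col < 0) | (col >= self.ncols) | (row < 0) | (row >= self.nrows)
        return np.where(bad, -1, row), np.where(bad, -1, col)

    def lon_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cellsize

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.nrows) + 0.5) * self.cellsize


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec, float]:
    """Read an Arc/Info ASCII grid: (data HxW with NaN at nodata, grid, nodata)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[n_header:], dtype=float, ndmin=2)
    grid = GridSpec(
        nrows=int(header["nrows"]),
        ncols=int(header["ncols"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
    )
    if data.shape != grid.shape:
        raise ValueError(f"{path}: data shape {data.shape} != header {grid.shape}")
    data = np.where(data == nodata, np.nan, data)
    return data, grid, nodata


def write_ascii_grid(
    path: str | Path,
    data: np.ndarray,
    grid: GridSpec,
    nodata: float = -9999.0,
    fmt: str = "%.6g",
) -> None:
    data = np.asarray(data, dtype=float)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} != grid shape {grid.shape}")
    out = np.where(np.isnan(data), nodata, data)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {grid.ncols}\nnrows {grid.nrows}\n"
            f"xllcorner {grid.xll:.10g}\nyllcorner {grid.yll:.10g}\n"
            f"cellsize {grid.cellsize:.10g}\nNODATA_value {nodata:.10g}\n"
        )
        np.savetxt(fh, out, fmt=fmt)


@dataclass
class ClimateStack:
    """K aligned environmental layers over one geographic grid.

    ``data`` has shape (K, nrows, ncols) with NaN marking nodata; the
    validity mask is shared across layers (any-NaN → cell invalid).
    """

    data: np.ndarray
    names: list[str]
    grid: GridSpec
    crs: str = WGS84

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (K, nrows, ncols)")
        if self.data.shape[0] != len(self.names):
            raise ValueError("one name per layer required")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("layer shape does not match grid")
        if self.data.shape[0] < 2:
            raise ValueError("a climate stack needs at least two layers")
        # propagate nodata: any invalid layer invalidates the cell everywhere
        invalid = np.isnan(self.data).any(axis=0)
        self.data[:, invalid] = np.nan

    @property
    def k(self) -> int:
        return self.data.shape[0]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean (nrows, ncols): True where all layers carry data."""
        return ~np.isnan(self.data[0])

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def values_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(values (n_valid, K), rows, cols) for every valid cell, row-major."""
        rows, cols = np.nonzero(self.valid_mask)
        return self.data[:, rows, cols].T, rows, cols

    def copy(self) -> "ClimateStack":
        return ClimateStack(self.data.copy(), list(self.names), self.grid, self.crs)

    def write(self, directory: str | Path, nodata: float = -9999.0) -> list[Path]:
        """Write one .asc file per layer into *directory*; returns the paths."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, name in enumerate(self.names):
            p = directory / f"{name}.asc"
            write_ascii_grid(p, self.data[i], self.grid, nodata=nodata)
            paths.append(p)
        return paths


def load_stack(paths: Sequence[str | Path], names: Sequence[str] | None = None) -> ClimateStack:
    """Load co-registered ASCII grid rasters into one stack.

    Grids must already be aligned: any shape/corner/cellsize mismatch is an
    error — there is deliberately no silent resampling.
    """
    paths = [Path(p) for p in paths]
    if len(paths) < 2:
        raise ValueError("need at least two raster layers")
    layers, grids = [], []
    for p in paths:
        data, grid, _ = read_ascii_grid(p)
        layers.append(data)
        grids.append(grid)
    ref = grids[0]
    for p, g in zip(paths[1:], grids[1:]):
        if g != ref:
            raise ValueError(
                f"raster alignment error: {p} grid {g} does not match {paths[0]} grid {ref}"
            )
    if names is None:
        names = [p.stem for p in paths]
    return ClimateStack(np.stack(layers), list(names), ref)


def extract_values(
    occurrences,
    stack: ClimateStack,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, str]]]:
    """Sample the stack at occurrence points.

    Returns ``(values, kept_index, dropped_log)`` where *values* is an
    (n_kept, K) matrix of cell values at the points' cells, *kept_index* the
    positional indices of the surviving records, and *dropped_log* records
    points that fell outside the grid or on nodata cells.  Raises if no point
    lands on a valid cell.
    """
    lon = np.asarray(occurrences.lon, dtype=float)
    lat = np.asarray(occurrences.lat, dtype=float)
    row, col = stack.grid.index_of(lon, lat)
    dropped: list[tuple[int, str]] = []
    keep = []
    for i in range(len(lon)):
        if row[i] < 0:
            dropped.append((i, "outside raster extent"))
        elif not stack.valid_mask[row[i], col[i]]:
            dropped.append((i, "nodata cell"))
        else:
            keep.append(i)
    if not keep:
        raise ValueError("all occurrence points fall outside valid raster cells")
    keep_arr = np.asarray(keep, dtype=int)
    values = stack.data[:, row[keep_arr], col[keep_arr]].T
    return values, keep_arr, dropped


@dataclass(frozen=True)
class EnvelopeBox:
    """Axis-aligned min–max climatic envelope over K variables (BIOCLIM box)."""

    lo: np.ndarray
    hi: np.ndarray
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "lo", np.asarray(self.lo, dtype=float))
        object.__setattr__(self, "hi", np.asarray(self.hi, dtype=float))
        if self.lo.shape != self.hi.shape or self.lo.ndim != 1:
            raise ValueError("lo/hi must be 1-D and of equal length")
        if np.any(self.lo > self.hi):
            raise ValueError("envelope has min > max for some variable")

    @property
    def k(self) -> int:
        return self.lo.size

    def contains(self, values: np.ndarray) -> np.ndarray:
        """Boolean vector: rows of *values* inside the box in every variable."""
        v = np.atleast_2d(np.asarray(values, dtype=float))
        return np.all((v >= self.lo) & (v <= self.hi), axis=1)


def fit_envelope(values: np.ndarray, names: Iterable[str] = ()) -> EnvelopeBox:
    """Rectangular envelope = exact column-wise min/max of occurrence values."""
    v = np.atleast_2d(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot fit an envelope to zero records")
    if np.isnan(v).any():
        raise ValueError("envelope training values contain NaN")
    return EnvelopeBox(v.min(axis=0), v.max(axis=0), tuple(names))


def apply_envelope_mask(stack: ClimateStack, box: EnvelopeBox) -> ClimateStack:
    """Mask out every cell with any variable outside the envelope box.

    The surviving domain is exactly the set of cells whose K-vector lies in
    the box, so any niche model fitted and projected inside it is enclosed in
    the envelope by construction.
    """
    if box.k != stack.k:
        raise ValueError(f"envelope has {box.k} variables, stack has {stack.k}")
    out = stack.copy()
    inside = np.ones(stack.grid.shape, dtype=bool)
    for i in range(stack.k):
        layer = out.data[i]
        with np.errstate(invalid="ignore"):
            inside &= (layer >= box.lo[i]) & (layer <= box.hi[i])
    out.data[:, ~inside] = np.nan
    return out


AUTHALIC_RADIUS_KM = 6371.0072


def cell_area_km2(grid: GridSpec, rows: np.ndarray) -> np.ndarray:
    """Spherical area (km²) of cells in the given rows (area varies with lat only).

    cell area = R² · Δλ · (sin φ_top − sin φ_bottom) with the authalic earth
    radius; error vs the ellipsoid is below 0.3%.
    """
    rows = np.asarray(rows)
    lat_top = grid.north - rows * grid.cellsize
    lat_bot = lat_top - grid.cellsize
    dlon = math.radians(grid.cellsize)
    return (
        AUTHALIC_RADIUS_KM**2
        * dlon
        * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )
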