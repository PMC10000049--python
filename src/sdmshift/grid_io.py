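"""ESRI ASCII grid I/O and aligned raster stacks.

Rasters are plain-text grids with a six-line header (``ncols``, ``nrows``,
``xllcorner``/``xllcenter``, ``yllcorner``/``yllcenter``, ``cellsize``,
``NODATA_value``) followed by ``nrows`` rows of ``ncols`` values, the first
row being the northernmost.  All coordinates are geographic (lon/lat decimal
degrees, unprojected); cell areas are computed with the exact spherical
formula rather than any projected approximation.

Two helper functions, :func:`cell_center` and :func:`cell_index`, are the
single place where row/col and lon/lat conventions meet: values are stored
north-to-south, cell lookup uses half-open intervals ``[edge, edge+cellsize)``
anchored at the lower-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0088

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class GridFormatError(ValueError):
    """Raised for malformed ESRI ASCII headers or bodies."""


class GridAlignmentError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass
class Grid:
    """A single raster layer on a geographic grid.

    ``values`` is an ``nrows x ncols`` float array whose first row is the
    northernmost; nodata cells carry ``nodata_value`` exactly.
    """

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise GridFormatError(
                f"values shape {self.values.shape} does not match header "
                f"({self.nrows}, {self.ncols})"
            )
        if self.cellsize <= 0:
            raise GridFormatError("cellsize must be positive")
        finite = np.isfinite(self.values)
        if not finite.all():
            raise GridFormatError("grid contains non-finite values")

    # -- masks ---------------------------------------------------------------

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is nodata."""
        return self.values == self.nodata_value

    @property
    def data(self) -> np.ndarray:
        """Values with nodata replaced by NaN (copy)."""
        out = self.values.copy()
        out[self.mask] = np.nan
        return out

    def header(self) -> tuple:
        return (self.ncols, self.nrows, self.xllcorner, self.yllcorner, self.cellsize)

    def same_header(self, other: "Grid", tol: float = 1e-9) -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and abs(self.xllcorner - other.xllcorner) <= tol
            and abs(self.yllcorner - other.yllcorner) <= tol
            and abs(self.cellsize - other.cellsize) <= tol
        )

    def copy_with(self, values: np.ndarray) -> "Grid":
        return Grid(self.ncols, self.nrows, self.xllcorner, self.yllcorner,
                    self.cellsize, self.nodata_value, np.asarray(values, dtype=float))


@dataclass
class GridStack:
    """Aligned named layers sharing one header and one nodata mask."""

    layers: dict[str, Grid]
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.layers:
            raise GridAlignmentError("a GridStack needs at least one layer")
        names = list(self.layers)
        ref = self.layers[names[0]]
        for name in names[1:]:
            if not ref.same_header(self.layers[name]):
                raise GridAlignmentError(f"layer {name!r} header differs from {names[0]!r}")
        unknown = self.categorical - set(names)
        if unknown:
            raise GridAlignmentError(f"categorical names not in stack: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def grid(self) -> Grid:
        """Reference layer carrying the shared geometry."""
        return next(iter(self.layers.values()))

    @property
    def mask(self) -> np.ndarray:
        """Shared nodata mask (True = nodata)."""
        m = np.zeros((self.grid.nrows, self.grid.ncols), dtype=bool)
        for g in self.layers.values():
            m |= g.mask
        return m

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.mask

    def continuous_names(self) -> list[str]:
        return [n for n in self.layers if n not in self.categorical]

    def subset(self, names: Iterable[str]) -> "GridStack":
        names = list(names)
        return GridStack({n: self.layers[n] for n in names},
                         categorical=self.categorical & set(names))

    def table(self) -> pd.DataFrame:
        """One row per valid cell: row, col, lon, lat, and every layer value."""
        valid = self.valid_mask
        rows, cols = np.nonzero(valid)
        lon, lat = cell_center(self.grid, rows, cols)
        out = pd.DataFrame({"row": rows, "col": cols, "lon": lon, "lat": lat})
        for name, g in self.layers.items():
            out[name] = g.values[rows, cols]
        return out


# -- I/O ---------------------------------------------------------------------

def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII grid.

    ``xllcenter``/``yllcenter`` headers are normalized to the corner
    convention by subtracting half a cell.  Values within 1e-6 relative of
    the nodata sentinel are snapped to it exactly.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().split("\n")

    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "xllcenter", "yllcorner",
            "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            body_start = i + 1
        else:
            break

    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GridFormatError(f"{path}: missing header key {key!r}")
    if "xllcorner" not in header and "xllcenter" not in header:
        raise GridFormatError(f"{path}: missing header key 'xllcorner'")
    if "yllcorner" not in header and "yllcenter" not in header:
        raise GridFormatError(f"{path}: missing header key 'yllcorner'")
    if "nodata_value" not in header:
        raise GridFormatError(f"{path}: missing header key 'nodata_value'")

    cellsize = header["cellsize"]
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cellsize / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cellsize / 2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header["nodata_value"]

    tokens = " ".join(lines[body_start:]).split()
    try:
        values = np.asarray(tokens, dtype=float)
    except ValueError as exc:
        raise GridFormatError(f"{path}: unreadable body: {exc}") from exc
    if values.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: body has {values.size} values, header promises {nrows * ncols}"
        )
    values = values.reshape(nrows, ncols)

    # snap float-formatted sentinels
    denom = max(abs(nodata), 1.0)
    near = np.abs(values - nodata) <= 1e-6 * denom
    values[near] = nodata

    return Grid(ncols, nrows, xll, yll, cellsize, nodata, values)


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a Grid as ESRI ASCII (corner-convention header, %.6g values)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata_value:g}\n")
        for row in grid.values:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


# -- geometry ----------------------------------------------------------------

def cell_center(grid: Grid, row, col):
    """Lon/lat of the center of cell (row, col); row 0 is the northern edge."""
    row = np.asarray(row)
    col = np.asarray(col)
    lon = grid.xllcorner + (col + 0.5) * grid.cellsize
    lat = grid.yllcorner + (grid.nrows - 1 - row + 0.5) * grid.cellsize
    return lon, lat


def cell_index(grid: Grid, lon, lat):
    """(row, col) of the cell containing (lon, lat).

    Half-open intervals [edge, edge+cellsize) anchored at the lower-left
    corner; points on a shared edge belong to the cell east/north of it.
    Returns (row, col, in_bounds) arrays.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    col = np.floor((lon - grid.xllcorner) / grid.cellsize).astype(int)
    row_from_bottom = np.floor((lat - grid.yllcorner) / grid.cellsize).astype(int)
    row = grid.nrows - 1 - row_from_bottom
    inb = (col >= 0) & (col < grid.ncols) & (row >= 0) & (row < grid.nrows)
    return row, col, inb


def cell_area_km2(grid: Grid, row_index) -> np.ndarray | float:
    """Exact spherical area (km²) of cells in the given row(s).

    area = R² · Δλ · (sin φ_top − sin φ_bottom); identical for all cells of
    one row, strictly decreasing as |latitude| increases.
    """
    row = np.asarray(row_index)
    if np.any(row < 0) or np.any(row >= grid.nrows):
        raise IndexError(f"row index out of range 0..{grid.nrows - 1}")
    lat_bottom = grid.yllcorner + (grid.nrows - 1 - row) * grid.cellsize
    lat_top = lat_bottom + grid.cellsize
    dlam = np.radians(grid.cellsize)
    area = EARTH_RADIUS_KM ** 2 * dlam * (
        np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bottom))
    )
    if np.isscalar(row_index):
        return float(area)
    return area


def area_grid_km2(grid: Grid) -> np.ndarray:
    """Per-cell areas broadcast to the full grid shape."""
    row_areas = cell_area_km2(grid, np.arange(grid.nrows))
    return np.repeat(row_areas[:, None], grid.ncols, axis=1)


# -- stacking and extraction -------------------------------------------------

def harmonize_stack(grids: Mapping[str, Grid], categorical: Iterable[str] = ()) -> GridStack:
    """Build a GridStack, applying the union-of-nodata mask to every layer.

    Mismatched headers are an error: inputs must be pre-aligned (no silent
    resampling).
    """
    names = list(grids)
    if not names:
        raise GridAlignmentError("no layers given")
    ref = grids[names[0]]
    bad = [n for n in names[1:] if not ref.same_header(grids[n])]
    if bad:
        raise GridAlignmentError(f"layers not aligned with {names[0]!r}: {bad}")

    union = np.zeros((ref.nrows, ref.ncols), dtype=bool)
    for g in grids.values():
        union |= g.mask
    out: dict[str, Grid] = {}
    for name in names:
        g = grids[name]
        vals = g.values.copy()
        vals[union] = g.nodata_value
        out[name] = g.copy_with(vals)
    return GridStack(out, categorical=set(categorical))


def extract_values(stack: GridStack, points) -> pd.DataFrame:
    """Per-point layer values for an (n, 2) array of lon/lat points.

    Out-of-bounds points and points in nodata cells are flagged, never a
    crash; flagged rows carry NaN layer values.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    grid = stack.grid
    row, col, inb = cell_index(grid, pts[:, 0], pts[:, 1])
    mask = stack.mask
    safe_r = np.clip(row, 0, grid.nrows - 1)
    safe_c = np.clip(col, 0, grid.ncols - 1)
    nodata = np.where(inb, mask[safe_r, safe_c], False)
    ok = inb & ~nodata

    out = pd.DataFrame({
        "lon": pts[:, 0], "lat": pts[:, 1],
        "row": np.where(inb, row, -1), "col": np.where(inb, col, -1),
        "in_bounds": inb, "nodata": nodata,
    })
    for name, g in stack.layers.items():
        vals = np.full(len(pts), np.nan)
        vals[ok] = g.values[row[ok], col[ok]]
        out[name] = vals
    return out
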