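"""Raster grids, ESRI ASCII I/O, block tessellation and zonal aggregation.

All rasters in a run share shape, cell size and origin; no resampling is
performed. Land-cover codes are fixed: 1 farmland, 2 forestland, 3 grassland,
4 water, 5 construction, 6 bare land.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LANDUSE_CODES = (1, 2, 3, 4, 5, 6)
LANDUSE_NAMES = {
    1: "farmland",
    2: "forestland",
    3: "grassland",
    4: "water",
    5: "construction",
    6: "bare",
}
N_CLASSES = 6

__all__ = [
    "LANDUSE_CODES",
    "LANDUSE_NAMES",
    "N_CLASSES",
    "Grid",
    "LandUseGrid",
    "ContinuousGrid",
    "AssessmentGrid",
    "read_raster",
    "write_raster",
    "tessellate",
    "zonal_stat",
    "class_proportions",
]


@dataclass
class Grid:
    """A georeferenced 2D raster. ``origin`` is the lower-left corner
    (ESRI ASCII convention); row 0 of ``values`` is the top row."""

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be a 2D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    def copy_with(self, values: np.ndarray) -> "Grid":
        return replace(self, values=values)


@dataclass
class LandUseGrid(Grid):
    """Categorical cover raster with integer codes 1..6 (or nodata)."""

    nodata: int = -9999

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int64, copy=False)
        valid = self.values[self.values != self.nodata]
        if valid.size and (valid.min() < 1 or valid.max() > N_CLASSES):
            raise ValueError("land-use codes must lie in 1..6")


@dataclass
class ContinuousGrid(Grid):
    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.float64, copy=False)
        valid = self.values[self.values != self.nodata]
        if valid.size and not np.all(np.isfinite(valid)):
            raise ValueError("non-finite values outside nodata")


@dataclass
class AssessmentGrid:
    """Cell-to-unit mapping from a block tessellation.

    ``unit_id`` assigns every cell a unit id (1-based, row-major over unit
    blocks); ``unit_index`` is a table with columns
    (unit_id, unit_row, unit_col, cell_count, partial).
    """

    unit_id: np.ndarray
    unit_km: float
    n_unit_rows: int
    n_unit_cols: int
    unit_index: pd.DataFrame = field(repr=False)

    @property
    def n_units(self) -> int:
        return self.n_unit_rows * self.n_unit_cols

    def unit_ids(self) -> np.ndarray:
        return self.unit_index["unit_id"].to_numpy()


# ---------------------------------------------------------------------------
# I/O — ESRI ASCII grid (plain text, portable, preserves georeference)
# ---------------------------------------------------------------------------

def write_raster(grid: Grid, path: str | Path) -> Path:
    """Write a grid as an ESRI ASCII raster. Returns the path written."""
    path = Path(path)
    nrows, ncols = grid.shape
    integral = np.issubdtype(grid.values.dtype, np.integer)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt="%d" if integral else "%.17g")
    return path


def read_raster(path: str | Path, kind: str = "auto") -> Grid:
    """Read an ESRI ASCII raster.

    ``kind`` is one of ``landuse``, ``continuous`` or ``auto`` (integer data
    in 1..6 becomes a :class:`LandUseGrid`, anything else continuous).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in ("ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"):
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    if "ncols" not in header or "nrows" not in header:
        raise ValueError(f"{path}: missing ESRI ASCII header")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(
            f"{path}: data shape {data.shape} does not match header")
    nodata = header.get("nodata_value", -9999)
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0))
    cell = header.get("cellsize", 1.0)
    is_integral = np.all(data == np.round(data))
    if kind == "landuse" or (
        kind == "auto" and is_integral
        and np.all(np.isin(data, list(LANDUSE_CODES) + [nodata]))
    ):
        return LandUseGrid(data.astype(np.int64), cell, origin, int(nodata))
    return ContinuousGrid(data, cell, origin, nodata)


def check_stack_alignment(grids: list[Grid]) -> None:
    """Raise if grids do not share shape, cell size and origin."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise ValueError(f"shape mismatch: {g.shape} vs {ref.shape}")
        if not math.isclose(g.cell_size, ref.cell_size):
            raise ValueError("cell-size mismatch in raster stack")
        if not np.allclose(g.origin, ref.origin):
            raise ValueError("origin mismatch in raster stack")


# ---------------------------------------------------------------------------
# Tessellation
# ---------------------------------------------------------------------------

def tessellate(grid: Grid, unit_km: float) -> AssessmentGrid:
    """Partition the raster into axis-aligned unit_km x unit_km blocks.

    Blocks are anchored at the raster origin (top-left in array space); edge
    blocks may be partial and are flagged. Unit ids are 1-based, row-major.
    """
    b = unit_km / grid.cell_size
    if b <= 0 or abs(b - round(b)) > 1e-9:
        raise ValueError(
            f"unit_km={unit_km} is not a positive multiple of "
            f"cell_size={grid.cell_size}")
    b = int(round(b))
    nrows, ncols = grid.shape
    n_ur = -(-nrows // b)
    n_uc = -(-ncols // b)
    rows = np.arange(nrows) // b
    cols = np.arange(ncols) // b
    unit_id = (rows[:, None] * n_uc + cols[None, :] + 1).astype(np.int64)

    valid = grid.valid_mask()
    counts = np.bincount(unit_id[valid].ravel(), minlength=n_ur * n_uc + 1)[1:]
    ur, uc = np.divmod(np.arange(n_ur * n_uc), n_uc)
    full = b * b
    index = pd.DataFrame({
        "unit_id": np.arange(1, n_ur * n_uc + 1),
        "unit_row": ur,
        "unit_col": uc,
        "cell_count": counts,
        "partial": (np.minimum((ur + 1) * b, nrows) - ur * b)
        * (np.minimum((uc + 1) * b, ncols) - uc * b) < full,
    })
    return AssessmentGrid(unit_id, unit_km, n_ur, n_uc, index)


# ---------------------------------------------------------------------------
# Zonal aggregation
# ---------------------------------------------------------------------------

def _zone_array(zones: AssessmentGrid | np.ndarray) -> np.ndarray:
    if isinstance(zones, AssessmentGrid):
        return zones.unit_id
    return np.asarray(zones)


def zonal_stat(
    grid: Grid,
    zones: AssessmentGrid | np.ndarray,
    stat: str = "mean",
) -> pd.Series:
    """Per-zone statistic of ``grid`` over zone labels.

    nodata cells are excluded; zones without valid cells get NaN. ``majority``
    breaks ties toward the lowest value (documented contract).
    """
    zarr = _zone_array(zones)
    if zarr.shape != grid.shape:
        raise ValueError("zone raster shape does not match grid")
    valid = grid.valid_mask()
    z = zarr[valid].ravel()
    v = grid.values[valid].ravel()
    zone_ids = np.unique(zarr)
    if stat in ("mean", "sum"):
        sums = np.zeros(zone_ids.max() + 1)
        np.add.at(sums, z, v.astype(np.float64))
        counts = np.bincount(z, minlength=zone_ids.max() + 1)
        with np.errstate(invalid="ignore"):
            out = sums if stat == "sum" else sums / counts
        vals = np.where(counts[zone_ids] > 0,
                        out[zone_ids],
                        0.0 if stat == "sum" else np.nan)
        if stat == "sum":
            vals = np.where(counts[zone_ids] > 0, vals, np.nan)
    elif stat == "majority":
        vals = np.full(zone_ids.size, np.nan)
        order = {zid: i for i, zid in enumerate(zone_ids)}
        df = pd.DataFrame({"z": z, "v": v})
        # lowest value wins ties: sort values ascending, keep first max count
        for zid, sub in df.groupby("z", sort=True):
            counts = sub["v"].value_counts()
            top = counts.max()
            vals[order[zid]] = min(c for c, n in counts.items() if n == top)
    else:
        raise ValueError(f"unsupported stat {stat!r}")
    return pd.Series(vals, index=pd.Index(zone_ids, name="zone_id"),
                     name=stat)


def class_proportions(
    landuse: LandUseGrid,
    zones: AssessmentGrid | np.ndarray,
) -> pd.DataFrame:
    """Per-zone area shares of the six cover classes.

    Rows sum to 1 for zones with valid cells; all-nodata zones yield NaN.
    """
    zarr = _zone_array(zones)
    if zarr.shape != landuse.shape:
        raise ValueError("zone raster shape does not match grid")
    valid = landuse.valid_mask()
    z = zarr[valid].ravel()
    v = landuse.values[valid].ravel()
    zone_ids = np.unique(zarr)
    nmax = int(zarr.max()) + 1
    shares = np.zeros((zone_ids.size, N_CLASSES))
    for ci, code in enumerate(LANDUSE_CODES):
        cnt = np.bincount(z[v == code], minlength=nmax)
        shares[:, ci] = cnt[zone_ids]
    totals = shares.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        shares = np.where(totals > 0, shares / totals, np.nan)
    return pd.DataFrame(
        shares,
        index=pd.Index(zone_ids, name="zone_id"),
        columns=[LANDUSE_NAMES[c] for c in LANDUSE_CODES],
    )
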