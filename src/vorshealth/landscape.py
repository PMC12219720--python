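"""Per-unit landscape structure metrics.

Eight metrics feed the organisation sub-index: Shannon diversity (SHDI),
area-weighted mean patch fractal dimension (AWMPFD), overall landscape
fragmentation (FI1, patch density), contagion (CONT), water/forest
fragmentation (FI2/FI3) and water/forest patch cohesion (COHESION1/2).
Formulas follow the FRAGSTATS definitions; fragmentation is patch density
(patches per km^2). Metrics are computed on each unit window in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import LANDUSE_CODES, AssessmentGrid, LandUseGrid, N_CLASSES

WATER_CODE = 4
FOREST_CODE = 2

_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
_STRUCT8 = np.ones((3, 3), bool)

METRIC_NAMES = ("SHDI", "AWMPFD", "FI1", "CONT",
                "FI2", "COHESION1", "FI3", "COHESION2")

#: default weights of the normalised metrics inside the organisation index
DEFAULT_EO_WEIGHTS = {
    "SHDI": 0.25, "AWMPFD": 0.10,
    "FI1": 0.25, "CONT": 0.10,
    "FI2": 0.10, "COHESION1": 0.05,
    "FI3": 0.10, "COHESION2": 0.05,
}

#: metrics whose normalisation is inverted (higher raw value = worse
#: organisation): the three fragmentation densities
INVERTED_METRICS = ("FI1", "FI2", "FI3")


@dataclass
class Patch:
    class_code: int
    area: int           # cells
    perimeter: int      # exposed cell edges


@dataclass
class PatchSet:
    patches: list[Patch]
    connectivity: int   # 4 or 8

    def __iter__(self):
        return iter(self.patches)

    def __len__(self) -> int:
        return len(self.patches)

    def restrict(self, class_code: int) -> "PatchSet":
        return PatchSet(
            [p for p in self.patches if p.class_code == class_code],
            self.connectivity)


def label_patches(
    window: np.ndarray,
    connectivity: int = 8,
    nodata: int = -9999,
) -> PatchSet:
    """Connected components of equal-class cells with exposed-edge perimeters.

    Perimeter counts cell edges facing a different class, nodata, or the
    window boundary.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    window = np.asarray(window)
    if window.size == 0:
        raise ValueError("empty window")
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    patches: list[Patch] = []
    for code in np.unique(window):
        if code == nodata:
            continue
        mask = window == code
        labels, n = ndimage.label(mask, structure=structure)
        if n == 0:
            continue
        areas = np.bincount(labels.ravel())[1:]
        # same-patch 4-neighbour contacts; perimeter = 4*area - 2*contacts
        contacts = np.zeros(n + 1, dtype=np.int64)
        h = (labels[:, :-1] == labels[:, 1:]) & (labels[:, :-1] > 0)
        v = (labels[:-1, :] == labels[1:, :]) & (labels[:-1, :] > 0)
        np.add.at(contacts, labels[:, :-1][h], 1)
        np.add.at(contacts, labels[:-1, :][v], 1)
        perims = 4 * areas - 2 * contacts[1:]
        patches.extend(
            Patch(int(code), int(a), int(p)) for a, p in zip(areas, perims))
    return PatchSet(patches, connectivity)


def shdi(shares: np.ndarray) -> float:
    """Shannon diversity: -sum p_i ln p_i over classes with p_i > 0."""
    p = np.asarray(shares, dtype=float)
    p = p[p > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log(p)).sum())


def awmpfd(patches: PatchSet, window_area: float) -> float:
    """Area-weighted mean patch fractal dimension.

    Each patch contributes 2*ln(0.25*p)/ln(a) weighted by a/window_area.
    Single-cell patches (ln a = 0) contribute the geometric lower bound 1.0.
    """
    if len(patches) == 0:
        raise ValueError("empty patch set")
    total = 0.0
    for p in patches:
        frac = 1.0 if p.area <= 1 else 2.0 * np.log(0.25 * p.perimeter) / np.log(p.area)
        total += frac * (p.area / window_area)
    return float(total)


def adjacency_counts(
    window: np.ndarray, nodata: int = -9999
) -> np.ndarray:
    """6x6 matrix of 4-neighbour cell adjacencies, double-count convention
    (each ordered pair counted once in each direction)."""
    window = np.asarray(window)
    g = np.zeros((N_CLASSES + 1, N_CLASSES + 1), dtype=np.int64)
    pairs = [
        (window[:, :-1], window[:, 1:]),
        (window[:-1, :], window[1:, :]),
    ]
    for a, b in pairs:
        ok = (a != nodata) & (b != nodata)
        np.add.at(g, (a[ok], b[ok]), 1)
        np.add.at(g, (b[ok], a[ok]), 1)
    return g[1:, 1:]


def contagion(window: np.ndarray, nodata: int = -9999) -> float:
    """FRAGSTATS contagion index in [0, 100].

    100*[1 + sum_i sum_k P'_ik ln P'_ik / (2 ln m)] with
    P'_ik = p_i * g_ik / sum_k g_ik over the m classes present.
    Single-class windows return 100 by convention.
    """
    window = np.asarray(window)
    vals = window[window != nodata]
    if vals.size < 2:
        raise ValueError("contagion needs at least 2 valid cells")
    codes = np.unique(vals)
    m = codes.size
    if m == 1:
        return 100.0
    p = np.array([(vals == c).mean() for c in codes])
    g = adjacency_counts(window, nodata)[np.ix_(codes - 1, codes - 1)]
    rowsum = g.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pprime = p[:, None] * np.where(rowsum > 0, g / rowsum, 0.0)
    nz = pprime > 0
    entropy = float((pprime[nz] * np.log(pprime[nz])).sum())
    return float(100.0 * (1.0 + entropy / (2.0 * np.log(m))))


def fragmentation_index(patches: PatchSet, area_km2: float) -> float:
    """Patch density: patches per km^2. Zero patches -> 0."""
    if area_km2 <= 0:
        raise ValueError("area must be positive")
    return len(patches) / area_km2


def cohesion(patches: PatchSet, total_cells: int) -> float:
    """Patch cohesion index of a single-class patch set, in [0, 100].

    [1 - sum(p)/sum(p*sqrt(a))] * [1 - 1/sqrt(Z)]^-1 * 100 with Z the
    window's total cell count. Absent class -> 0 by convention.
    """
    if total_cells < 2:
        raise ValueError("cohesion needs at least 2 cells in the window")
    if len(patches) == 0:
        return 0.0
    sp = sum(p.perimeter for p in patches)
    spa = sum(p.perimeter * np.sqrt(p.area) for p in patches)
    return float((1.0 - sp / spa) / (1.0 - 1.0 / np.sqrt(total_cells)) * 100.0)


def window_metrics(
    window: np.ndarray,
    cell_size_km: float = 1.0,
    connectivity: int = 8,
    nodata: int = -9999,
) -> dict[str, float]:
    """All eight raw metrics for one unit window."""
    window = np.asarray(window)
    valid = window != nodata
    n_valid = int(valid.sum())
    if n_valid == 0:
        return {m: np.nan for m in METRIC_NAMES}
    area_km2 = n_valid * cell_size_km**2
    patches = label_patches(window, connectivity, nodata)
    shares = np.array([(window[valid] == c).mean() for c in LANDUSE_CODES])
    water = patches.restrict(WATER_CODE)
    forest = patches.restrict(FOREST_CODE)
    out = {
        "SHDI": shdi(shares),
        "AWMPFD": awmpfd(patches, n_valid),
        "FI1": fragmentation_index(patches, area_km2),
        "CONT": contagion(window, nodata) if n_valid >= 2 else 100.0,
        "FI2": fragmentation_index(water, area_km2),
        "COHESION1": cohesion(water, n_valid) if n_valid >= 2 else 0.0,
        "FI3": fragmentation_index(forest, area_km2),
        "COHESION2": cohesion(forest, n_valid) if n_valid >= 2 else 0.0,
    }
    return out


def unit_metrics(
    landuse: LandUseGrid,
    units: AssessmentGrid,
    connectivity: int = 8,
) -> pd.DataFrame:
    """Raw landscape metrics per assessment unit (rows = unit ids).

    Units without valid cells get NaN rows. Windows are cut along unit
    block bounds; no cross-unit adjacency.
    """
    b = int(round(units.unit_km / landuse.cell_size))
    nrows, ncols = landuse.shape
    rows = []
    for rec in units.unit_index.itertuples(index=False):
        r0, c0 = rec.unit_row * b, rec.unit_col * b
        win = landuse.values[r0:min(r0 + b, nrows), c0:min(c0 + b, ncols)]
        rows.append(window_metrics(
            win, landuse.cell_size, connectivity, landuse.nodata))
    df = pd.DataFrame(rows, index=pd.Index(units.unit_ids(), name="unit_id"))
    return df[list(METRIC_NAMES)]
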