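"""Synthetic scenario generation with known ground truth.

Produces a multi-year categorical land-cover series, cover-correlated NDVI,
nine driver surfaces with designed stratified-variance relationships, and a
county partition. Everything is a pure function of (parameters, seed): the
master seed is expanded into per-component sub-seeds with
``numpy.random.SeedSequence(master_seed).spawn`` in a fixed order
(land use, NDVI, drivers, counties, hotspot).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import (LANDUSE_CODES, LANDUSE_NAMES, ContinuousGrid,
                    LandUseGrid, N_CLASSES)

DRIVER_IDS = tuple(f"X{i}" for i in range(1, 10))

#: NDVI mean per cover class (farmland, forest, grass, water, constr, bare)
NDVI_CLASS_MEANS = {1: 0.55, 2: 0.8, 3: 0.6, 4: 0.05, 5: 0.2, 6: 0.15}

DEFAULT_CLASS_TARGETS = {
    "farmland": 0.35, "forestland": 0.35, "grassland": 0.10,
    "water": 0.10, "construction": 0.07, "bare": 0.03,
}

DEFAULT_DESIGNED_Q = {
    "X1": 0.05, "X2": 0.10, "X3": 0.08, "X4": 0.10, "X5": 0.12,
    "X6": 0.20, "X7": 0.05, "X8": 0.35, "X9": 0.30,
}

_NAME_TO_CODE = {v: k for k, v in LANDUSE_NAMES.items()}


@dataclass
class GroundTruth:
    class_proportions_per_time: pd.DataFrame
    planted_hotspot_mask: np.ndarray
    designed_q: dict[str, float]
    driver_strata: dict[str, np.ndarray] = field(repr=False)
    transition_matrix: np.ndarray = field(repr=False)


@dataclass
class SyntheticScenario:
    landuse_series: list[LandUseGrid]
    ndvi_series: list[ContinuousGrid]
    drivers: dict[str, ContinuousGrid]
    county_labels: np.ndarray
    truth: GroundTruth
    cell_size: float = 1.0


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def generate_gaussian_field(
    shape: tuple[int, int],
    correlation_range: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Zero-mean unit-variance spatially autocorrelated surface.

    White noise smoothed by a Gaussian kernel with sigma =
    ``correlation_range`` cells (0 = pure white noise), then re-standardised.
    Identical (shape, range, seed) gives bitwise-identical output.
    """
    if len(shape) != 2 or shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive 2D")
    if correlation_range < 0:
        raise ValueError("correlation_range must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    if correlation_range > 0:
        z = ndimage.gaussian_filter(z, sigma=correlation_range,
                                    mode="reflect")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _targets_vector(class_targets: dict[str, float] | dict[int, float]):
    t = np.zeros(N_CLASSES)
    for key, v in class_targets.items():
        code = _NAME_TO_CODE[key] if isinstance(key, str) else int(key)
        t[code - 1] = v
    if abs(t.sum() - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    return t


def threshold_field(field: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Categorise a latent field at target quantiles -> codes 1..6.

    Cell-rank thresholding realises the target proportions to within one
    cell per class.
    """
    n = field.size
    order = np.argsort(field, axis=None, kind="stable")
    bounds = np.round(np.cumsum(targets) * n).astype(int)
    out = np.empty(n, dtype=np.int64)
    start = 0
    for code, end in enumerate(bounds, start=1):
        out[order[start:end]] = code
        start = end
    return out.reshape(field.shape)


def generate_landuse_series(
    shape: tuple[int, int],
    class_targets: dict[str, float] | dict[int, float],
    transition_matrix: np.ndarray,
    T: int,
    seed: int | np.random.SeedSequence,
    correlation_range: float = 6.0,
    cell_size: float = 1.0,
) -> list[LandUseGrid]:
    """Land-cover series: thresholded latent field at t=0, then spatially
    clustered class transitions following ``transition_matrix`` per step.

    For each off-diagonal entry P(i -> j) the expected number of class-i
    cells is converted, preferring cells with high smoothed class-j density
    (growth clusters around existing class-j areas).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (N_CLASSES, N_CLASSES):
        raise ValueError("transition matrix must be 6x6")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("transition matrix rows must sum to 1")
    targets = _targets_vector(class_targets)
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    sub = ss.spawn(T)
    latent = generate_gaussian_field(shape, correlation_range, sub[0])
    current = threshold_field(latent, targets)
    series = [LandUseGrid(current.copy(), cell_size)]
    for t in range(1, T):
        rng = np.random.default_rng(sub[t])
        nxt = current.copy()
        for i in range(1, N_CLASSES + 1):
            cells = np.flatnonzero(current.ravel() == i)
            if cells.size == 0:
                continue
            moves = P[i - 1].copy()
            moves[i - 1] = 0.0
            for j in np.flatnonzero(moves > 0) + 1:
                n_conv = int(round(moves[j - 1] * cells.size))
                if n_conv == 0:
                    continue
                density = ndimage.gaussian_filter(
                    (current == j).astype(float), sigma=2.0, mode="reflect")
                score = density.ravel()[cells] + 0.05 * rng.random(cells.size)
                chosen = cells[np.argsort(-score, kind="stable")[:n_conv]]
                nxt.ravel()[chosen] = j
                cells = np.setdiff1d(cells, chosen, assume_unique=True)
        current = nxt
        series.append(LandUseGrid(current.copy(), cell_size))
    return series


def generate_ndvi(
    landuse: LandUseGrid,
    seed: int | np.random.SeedSequence,
    noise_sd: float = 0.08,
    correlation_range: float = 3.0,
) -> ContinuousGrid:
    """NDVI surface correlated with cover class, clipped to [-1, 1]."""
    means = np.zeros(N_CLASSES + 1)
    for code, m in NDVI_CLASS_MEANS.items():
        means[code] = m
    base = means[landuse.values]
    noise = generate_gaussian_field(landuse.shape, correlation_range, seed)
    return ContinuousGrid(np.clip(base + noise_sd * noise, -1.0, 1.0),
                          landuse.cell_size, landuse.origin)


def make_stratified_driver(
    strata: np.ndarray,
    designed_q: float,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Surface whose strata explain exactly ``designed_q`` of its variance.

    Stratum means are spread linearly; within-stratum noise is centred per
    stratum (so realised stratum means are exact) and rescaled post hoc so
    SSB/(SSB+SSW) equals designed_q in the realised sample.
    """
    if not 0.0 <= designed_q <= 1.0:
        raise ValueError("designed_q must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels, inv = np.unique(strata, return_inverse=True)
    inv = inv.reshape(strata.shape)
    L = labels.size
    noise = rng.standard_normal(strata.shape)
    # centre noise within each stratum: stratum means stay exact
    nsum = np.bincount(inv.ravel(), weights=noise.ravel())
    ncnt = np.bincount(inv.ravel())
    noise = noise - (nsum / ncnt)[inv]
    ssw0 = float((noise**2).sum())
    if designed_q == 0.0:
        return noise
    stratum_means = np.linspace(0.0, 1.0, L)[inv]
    gm = stratum_means.mean()
    ssb = float(((stratum_means - gm) ** 2).sum())
    if designed_q == 1.0:
        return stratum_means
    alpha = np.sqrt(ssb * (1.0 - designed_q) / (designed_q * ssw0))
    return stratum_means + alpha * noise


def generate_drivers(
    landuse_series: list[LandUseGrid],
    designed_q: dict[str, float],
    seed: int | np.random.SeedSequence,
    n_strata: int = 5,
) -> tuple[dict[str, ContinuousGrid], dict[str, np.ndarray]]:
    """Nine driver surfaces with designed explanatory power.

    X1..X7 stratify smooth random base fields; X8 (population density) and
    X9 (land urbanisation) stratify the smoothed construction-class density
    of the final land-use grid, so they co-vary with built-up areas.
    Returns (drivers, generating strata).
    """
    bad = {k: v for k, v in designed_q.items()
           if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"designed_q outside [0,1]: {bad}")
    unknown = set(designed_q) - set(DRIVER_IDS)
    if unknown:
        raise ValueError(f"unknown driver ids: {sorted(unknown)}")
    ref = landuse_series[-1]
    shape = ref.shape
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    subs = iter(ss.spawn(2 * len(DRIVER_IDS)))
    constr_density = ndimage.gaussian_filter(
        (ref.values == 5).astype(float), sigma=4.0, mode="reflect")
    drivers: dict[str, ContinuousGrid] = {}
    strata_out: dict[str, np.ndarray] = {}
    for did in DRIVER_IDS:
        if did not in designed_q:
            continue
        s_base = next(subs)
        s_noise = next(subs)
        if did in ("X8", "X9"):
            base = constr_density + 1e-9 * generate_gaussian_field(
                shape, 0, s_base)  # tiny jitter breaks quantile ties
        else:
            base = generate_gaussian_field(shape, 8.0, s_base)
        qs = np.quantile(base, np.linspace(0, 1, n_strata + 1)[1:-1])
        strata = np.searchsorted(qs, base, side="left") + 1
        surf = make_stratified_driver(strata, designed_q[did], s_noise)
        drivers[did] = ContinuousGrid(surf, ref.cell_size, ref.origin)
        strata_out[did] = strata
    return drivers, strata_out


def generate_counties(
    shape: tuple[int, int],
    n_counties: int,
    seed: int | np.random.SeedSequence,
) -> np.ndarray:
    """Voronoi partition of the raster into labelled counties 1..n.

    Nearest-seed assignment on cell centres (ties to the lowest label);
    every county is nonempty and connected.
    """
    n_cells = shape[0] * shape[1]
    if n_counties < 1 or n_counties > n_cells:
        raise ValueError("n_counties must lie in [1, number of cells]")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_counties, replace=False)
    sr, sc = np.divmod(flat, shape[1])
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                         indexing="ij")
    d2 = ((rr[..., None] - sr) ** 2 + (cc[..., None] - sc) ** 2)
    labels = np.argmin(d2, axis=-1).astype(np.int64) + 1
    return _reattach_slivers(labels, n_counties)


def _reattach_slivers(labels: np.ndarray, n_counties: int) -> np.ndarray:
    """Discretised Voronoi cells can strand single-cell slivers; merge any
    non-largest component into an adjacent county until all are connected."""
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    for _ in range(100):
        dirty = False
        for lab in range(1, n_counties + 1):
            comp, n = ndimage.label(labels == lab, structure=struct)
            if n <= 1:
                continue
            dirty = True
            sizes = np.bincount(comp.ravel())[1:]
            keep = int(np.argmax(sizes)) + 1
            for ci in range(1, n + 1):
                if ci == keep:
                    continue
                sliver = comp == ci
                ring = ndimage.binary_dilation(sliver, struct) & ~sliver
                nbr_labels = labels[ring]
                nbr_labels = nbr_labels[nbr_labels != lab]
                if nbr_labels.size:
                    labels[sliver] = np.bincount(nbr_labels).argmax()
        if not dirty:
            break
    return labels


def plant_hotspot(
    grid: ContinuousGrid,
    mask: np.ndarray,
    contrast_sd: float = 4.0,
) -> ContinuousGrid:
    """Add ``contrast_sd`` standard deviations to the masked cells."""
    sd = grid.values[grid.valid_mask()].std()
    vals = grid.values + np.where(mask, contrast_sd * sd, 0.0)
    return ContinuousGrid(vals, grid.cell_size, grid.origin, grid.nodata)


# ---------------------------------------------------------------------------
# full scenario
# ---------------------------------------------------------------------------

def default_transition_matrix() -> np.ndarray:
    """Mild urban-expansion dynamics: farmland/grassland/bare leak into
    construction, small farmland-forest exchange."""
    P = np.eye(N_CLASSES)
    conv = {(1, 5): 0.02, (3, 5): 0.015, (6, 5): 0.03,
            (1, 2): 0.005, (2, 1): 0.003}
    for (i, j), p in conv.items():
        P[i - 1, j - 1] = p
        P[i - 1, i - 1] -= p
    return P


def generate_scenario(
    shape: tuple[int, int] = (200, 200),
    T: int = 5,
    n_counties: int = 64,
    class_targets: dict[str, float] | None = None,
    transition_matrix: np.ndarray | None = None,
    designed_q: dict[str, float] | None = None,
    seed: int = 0,
    cell_size: float = 1.0,
    hotspot_units: int = 8,
    unit_km: float = 3.0,
    hotspot_contrast_sd: float = 4.0,
) -> SyntheticScenario:
    """Complete synthetic scenario with ground truth.

    A square block of whole assessment units in the upper-left quadrant is
    planted as an NDVI hotspot in every year (recorded in the truth mask).
    """
    targets = DEFAULT_CLASS_TARGETS if class_targets is None else class_targets
    P = (default_transition_matrix() if transition_matrix is None
         else np.asarray(transition_matrix, dtype=float))
    dq = dict(DEFAULT_DESIGNED_Q if designed_q is None else designed_q)
    master = np.random.SeedSequence(seed)
    ss_lu, ss_ndvi, ss_drv, ss_cty, ss_hot = master.spawn(5)

    landuse = generate_landuse_series(
        shape, targets, P, T, ss_lu, cell_size=cell_size)

    b = int(round(unit_km / cell_size))
    side = hotspot_units * b
    r0 = b * 2
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r0 + side, r0:r0 + side] = True

    ndvi = []
    for lu, s in zip(landuse, ss_ndvi.spawn(T)):
        g = generate_ndvi(lu, s)
        g = plant_hotspot(g, mask, hotspot_contrast_sd)
        # planting may exceed the NDVI range; clip (unit-mean contrast stays)
        g.values = np.clip(g.values, -1.0, 1.0)
        ndvi.append(g)

    drivers, strata = generate_drivers(landuse, dq, ss_drv)
    counties = generate_counties(shape, n_counties, ss_cty)

    props = pd.DataFrame(
        [[(lu.values == c).mean() for c in LANDUSE_CODES] for lu in landuse],
        columns=[LANDUSE_NAMES[c] for c in LANDUSE_CODES],
    )
    props.index.name = "timepoint"
    truth = GroundTruth(props, mask, dq, strata, P)
    return SyntheticScenario(landuse, ndvi, drivers, counties, truth,
                             cell_size)
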