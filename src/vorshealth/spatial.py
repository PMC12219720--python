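"""Global spatial autocorrelation and local hot/cold-spot statistics on the
assessment-unit lattice.

Moran's I uses the analytic randomisation-assumption variance for its z and
two-sided p; an optional seeded permutation p-value is available. Gi* uses
self-inclusive weights and the population standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse, stats

HOTSPOT_CLASSES = ("cold99", "cold95", "cold90", "ns",
                   "hot90", "hot95", "hot99")
_Z_THRESHOLDS = (1.65, 1.96, 2.58)


@dataclass
class SpatialWeights:
    """Sparse spatial weight matrix over n observations.

    ``w`` excludes the diagonal (no self-neighbours, as Moran's I requires);
    Gi* adds self-inclusion internally.
    """

    w: sparse.csr_matrix
    scheme: str
    row_standardised: bool

    @property
    def n(self) -> int:
        return self.w.shape[0]


@dataclass
class MoranResult:
    I: float
    expected: float
    z: float
    p: float


def build_weights(
    n_rows: int,
    n_cols: int,
    scheme: str = "queen",
    row_standardise: bool = True,
    mask: np.ndarray | None = None,
) -> SpatialWeights:
    """Contiguity weights for a regular unit lattice (row-major order).

    ``mask`` (n_rows x n_cols boolean) drops missing units; dropped units
    keep their index but have empty rows/columns.
    """
    if n_rows * n_cols < 2:
        raise ValueError("need at least 2 units")
    if scheme not in ("rook", "queen"):
        raise ValueError(f"unknown scheme {scheme!r}")
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if scheme == "queen":
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    idx = np.arange(n_rows * n_cols).reshape(n_rows, n_cols)
    ok = np.ones((n_rows, n_cols), bool) if mask is None else np.asarray(mask)
    rows, cols, data = [], [], []
    for dr, dc in offsets:
        src = idx[max(0, -dr):n_rows - max(0, dr),
                  max(0, -dc):n_cols - max(0, dc)]
        dst = idx[max(0, dr):n_rows - max(0, -dr),
                  max(0, dc):n_cols - max(0, -dc)]
        valid = ok.ravel()[src.ravel()] & ok.ravel()[dst.ravel()]
        rows.append(src.ravel()[valid])
        cols.append(dst.ravel()[valid])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = sparse.csr_matrix(
        (np.ones(rows.size), (rows, cols)),
        shape=(n_rows * n_cols, n_rows * n_cols))
    if row_standardise:
        rs = np.asarray(w.sum(axis=1)).ravel()
        inv = np.divide(1.0, rs, out=np.zeros_like(rs), where=rs > 0)
        w = sparse.diags(inv) @ w
    return SpatialWeights(w.tocsr(), scheme, row_standardise)


def morans_i(
    values: np.ndarray,
    weights: SpatialWeights,
    permutations: int = 0,
    seed: int | None = None,
) -> MoranResult:
    """Global Moran's I with analytic randomisation z and two-sided p.

    If ``permutations`` > 0 the p-value is replaced by the seeded
    permutation pseudo p-value (one-sided, folded to two sides).
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    w = weights.w
    if not finite.all():
        keep = np.flatnonzero(finite)
        w = w[keep][:, keep]
        x = x[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    z = x - x.mean()
    m2 = (z * z).sum()
    if m2 == 0:
        raise ValueError("constant values: Moran's I undefined")
    s0 = w.sum()
    I = (n / s0) * float(z @ (w @ z)) / m2

    wt = w.T.tocsr()
    s1 = 0.5 * float((w + wt).power(2).sum())
    rowsums = np.asarray(w.sum(axis=1)).ravel()
    colsums = np.asarray(w.sum(axis=0)).ravel()
    s2 = float(((rowsums + colsums) ** 2).sum())
    e_i = -1.0 / (n - 1)
    b2 = n * (z**4).sum() / m2**2
    num = (n * ((n * n - 3 * n + 3) * s1 - n * s2 + 3 * s0 * s0)
           - b2 * ((n * n - n) * s1 - 2 * n * s2 + 6 * s0 * s0))
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0 * s0) - e_i * e_i
    zscore = (I - e_i) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zscore))
    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            zp = rng.permutation(z)
            Ip = (n / s0) * float(zp @ (w @ zp)) / m2
            if abs(Ip - e_i) >= abs(I - e_i):
                count += 1
        p = (count + 1) / (permutations + 1)
    return MoranResult(float(I), e_i, float(zscore), float(p))


def getis_ord_gstar(values: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Per-unit Gi* z-scores (self-inclusive neighbourhoods).

    z_i = (sum_j w_ij x_j - xbar W_i) / (S * sqrt((n sum w_ij^2 - W_i^2)/(n-1)))
    with S the population standard deviation. NaN inputs yield NaN.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    n = int(finite.sum())
    if n < 3:
        raise ValueError("need at least 3 observations")
    xv = np.where(finite, x, 0.0)
    wstar = weights.w + sparse.eye(weights.n, format="csr")
    # zero out columns of missing units so they contribute nothing
    col_mask = sparse.diags(finite.astype(float))
    wstar = (wstar @ col_mask).tocsr()
    xbar = x[finite].mean()
    s = x[finite].std()  # population SD
    if s == 0:
        raise ValueError("constant values: Gi* undefined")
    wi = np.asarray(wstar.sum(axis=1)).ravel()
    wi2 = np.asarray(wstar.power(2).sum(axis=1)).ravel()
    num = wstar @ xv - xbar * wi
    denom = s * np.sqrt(np.maximum(n * wi2 - wi**2, 0.0) / (n - 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        zi = num / denom
    zi[~finite] = np.nan
    return zi


def classify_hotspots(z: np.ndarray) -> np.ndarray:
    """Map Gi* z-scores to the seven-tier hot/cold-spot classes
    (thresholds 1.65 / 1.96 / 2.58)."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, "ns", dtype=object)
    t90, t95, t99 = _Z_THRESHOLDS
    out[z >= t90] = "hot90"
    out[z >= t95] = "hot95"
    out[z >= t99] = "hot99"
    out[z <= -t90] = "cold90"
    out[z <= -t95] = "cold95"
    out[z <= -t99] = "cold99"
    out[~np.isfinite(z)] = "ns"
    return out
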