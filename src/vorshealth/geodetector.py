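"""Variance-based driver detection over discretised strata.

The q statistic is 1 minus the ratio of within-stratum to total variance
(population variances). Interaction detection computes q on the overlay of
two stratifications and classifies the result against the individual q
values into five mutually exclusive categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import jenks_breaks, classify

INTERACTION_TYPES = (
    "nonlinear enhancement",
    "dual-factor enhancement",
    "independence",
    "single-factor nonlinear attenuation",
    "nonlinear attenuation",
)

DEFAULT_TOL = 1e-6


@dataclass
class QResult:
    q: float
    strata_count: int
    p: float
    strata_sizes: np.ndarray = field(repr=False)
    strata_vars: np.ndarray = field(repr=False)

    def recompute_q(self) -> float:
        """q from the stored strata (consistency check)."""
        N = self.strata_sizes.sum()
        total = self._total_var
        return 1.0 - float(
            (self.strata_sizes * self.strata_vars).sum()) / (N * total)

    _total_var: float = field(default=0.0, repr=False)


@dataclass
class InteractionResult:
    q1: float
    q2: float
    q12: float
    type: str


def discretize(
    values: np.ndarray,
    k: int = 5,
    method: str = "jenks",
) -> np.ndarray:
    """Stratify continuous values into labels 1..k.

    Methods: ``jenks`` (default, natural breaks), ``quantile``,
    ``equal-interval``. NaN -> label 0.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if k < 2:
        raise ValueError("k must be at least 2")
    if np.unique(finite).size < k:
        raise ValueError("not enough distinct values to form k strata")
    if method == "jenks":
        breaks = jenks_breaks(finite, k)
    elif method == "quantile":
        qs = np.quantile(finite, np.linspace(0, 1, k + 1)[1:-1])
        breaks = np.unique(qs)
    elif method == "equal-interval":
        breaks = np.linspace(finite.min(), finite.max(), k + 1)[1:-1]
    else:
        raise ValueError(f"unknown method {method!r}")
    return classify(x, breaks)


def factor_q(y: np.ndarray, strata: np.ndarray,
             permutations: int = 0, seed: int | None = None) -> QResult:
    """q = 1 - [sum_h N_h var_h] / [N var] with population variances.

    Significance comes from the noncentral-F transformation
    F = ((N-L)/(L-1)) * q/(1-q); set ``permutations`` for a seeded
    permutation p-value instead.
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(strata)
    ok = np.isfinite(y) & (s != 0)
    y, s = y[ok], s[ok]
    N = y.size
    if N < 2:
        raise ValueError("need at least 2 observations")
    total_var = float(y.var())  # population variance
    if total_var == 0:
        raise ValueError("zero total variance: q undefined")
    labels, inv = np.unique(s, return_inverse=True)
    L = labels.size
    sizes = np.bincount(inv)
    sums = np.bincount(inv, weights=y)
    sums2 = np.bincount(inv, weights=y * y)
    means = sums / sizes
    variances = sums2 / sizes - means**2
    ssw = float((sizes * variances).sum())
    q = 1.0 - ssw / (N * total_var)
    q = min(max(q, 0.0), 1.0)

    if permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(permutations):
            qp = _q_only(y, rng.permutation(inv), sizes.size)
            if qp >= q:
                count += 1
        p = (count + 1) / (permutations + 1)
    elif L < 2 or N <= L:
        p = np.nan
    elif q >= 1.0:
        p = 0.0
    else:
        F = (N - L) / (L - 1) * q / (1.0 - q)
        lam = (means**2 * sizes).sum() - (
            np.sqrt(sizes) * means).sum() ** 2 / N
        lam /= total_var
        p = float(stats.ncf.sf(F, L - 1, N - L, max(lam, 0.0)))
    return QResult(q, L, p, sizes, variances, _total_var=total_var)


def _q_only(y: np.ndarray, inv: np.ndarray, L: int) -> float:
    sizes = np.bincount(inv, minlength=L)
    sums = np.bincount(inv, weights=y, minlength=L)
    sums2 = np.bincount(inv, weights=y * y, minlength=L)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(sizes > 0, sums / np.maximum(sizes, 1), 0.0)
        ssw = (sums2 - sizes * means**2).sum()
    return 1.0 - ssw / (y.size * y.var())


def overlay_strata(strata1: np.ndarray, strata2: np.ndarray) -> np.ndarray:
    """Cross-product stratification: one label per occupied (s1, s2) cell.

    Observations missing in either stratification (label 0) get label 0.
    """
    s1 = np.asarray(strata1)
    s2 = np.asarray(strata2)
    if s1.shape != s2.shape:
        raise ValueError("stratifications must align")
    ok = (s1 != 0) & (s2 != 0)
    pairs = s1.astype(np.int64) * (s2.max() + 1) + s2
    _, labels = np.unique(pairs[ok], return_inverse=True)
    out = np.zeros(s1.shape, dtype=np.int64)
    out[ok] = labels + 1
    return out


def interaction_q(
    y: np.ndarray, strata1: np.ndarray, strata2: np.ndarray
) -> QResult:
    """q on the overlay (cross-product) of two stratifications."""
    return factor_q(y, overlay_strata(strata1, strata2))


def classify_interaction(
    q1: float, q2: float, q12: float, tol: float = DEFAULT_TOL
) -> str:
    """Five-way interaction taxonomy on (q1, q2, q12).

    The decision cascade is exhaustive and mutually exclusive; boundary
    cases within ``tol`` resolve toward the weaker claim (independence at
    the sum boundary, attenuation at the max/min boundaries).
    """
    for v in (q1, q2, q12):
        if not (0.0 <= v <= 1.0):
            raise ValueError("q values must lie in [0, 1]")
    total = q1 + q2
    lo, hi = min(q1, q2), max(q1, q2)
    if q12 > total + tol:
        return "nonlinear enhancement"
    if q12 >= total - tol:
        return "independence"
    if q12 > hi + tol:
        return "dual-factor enhancement"
    if q12 >= lo - tol:
        return "single-factor nonlinear attenuation"
    return "nonlinear attenuation"


def significance_stars(p: float) -> str:
    """*** p<0.01, ** p<0.05, * p<0.1, blank otherwise (NaN -> blank)."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def factor_table(
    y: np.ndarray,
    drivers: dict[str, np.ndarray],
    k: int = 5,
    method: str = "jenks",
) -> pd.DataFrame:
    """q/p/stars per driver after discretisation."""
    rows = []
    for name, x in drivers.items():
        strata = discretize(x, k=k, method=method)
        res = factor_q(y, strata)
        rows.append({"driver": name, "q": res.q, "p": res.p,
                     "stars": significance_stars(res.p)})
    return pd.DataFrame(rows)


def interaction_table(
    y: np.ndarray,
    drivers: dict[str, np.ndarray],
    k: int = 5,
    method: str = "jenks",
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Pairwise interaction q and taxonomy over all driver pairs."""
    names = list(drivers)
    strata = {n: discretize(drivers[n], k=k, method=method) for n in names}
    qs = {n: factor_q(y, strata[n]).q for n in names}
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            q12 = interaction_q(y, strata[a], strata[b]).q
            rows.append({
                "driver1": a, "driver2": b,
                "q1": qs[a], "q2": qs[b], "q12": q12,
                "type": classify_interaction(qs[a], qs[b], q12, tol),
            })
    return pd.DataFrame(rows)
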