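"""Composite health indices and natural-breaks classification.

PH is the geometric mean of vigour (EV), organisation (EO) and resilience
(ER); the overall index is HI = sqrt(PH * CESI). Classification into five
ordinal levels uses exact Fisher-Jenks natural breaks (right-closed
intervals), or the fixed published breakpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is an install requirement
    njit = lambda *a, **k: (lambda f: f)  # noqa: E731

from .grids import LANDUSE_NAMES
from .landscape import DEFAULT_EO_WEIGHTS, INVERTED_METRICS, METRIC_NAMES

#: Default per-class (resistance, resilience) coefficients. The published
#: model cites external sources without printing values; these are plausible
#: defaults with forest > water > grassland > farmland > bare > construction.
DEFAULT_RESILIENCE = {
    "farmland": (0.5, 0.6),
    "forestland": (0.9, 0.8),
    "grassland": (0.7, 0.7),
    "water": (0.8, 0.7),
    "construction": (0.2, 0.2),
    "bare": (0.3, 0.3),
}

#: Fixed HI breakpoints published for the five-level scale
#: (low / relatively low / moderate / fairly good / excellent).
FIXED_HI_BREAKS = (0.174, 0.254, 0.324, 0.493)

LEVEL_LABELS = {1: "low", 2: "relatively low", 3: "moderate",
                4: "fairly good", 5: "excellent"}

_CLASS_COLS = [LANDUSE_NAMES[c] for c in sorted(LANDUSE_NAMES)]

__all__ = [
    "DEFAULT_RESILIENCE", "FIXED_HI_BREAKS", "LEVEL_LABELS",
    "minmax_normalize", "compute_ev", "compute_eo", "compute_er",
    "compute_ph", "compute_hi", "jenks_breaks", "classify",
]


def minmax_normalize(
    values: np.ndarray,
    invert: bool = False,
    domain_min: float | None = None,
    domain_max: float | None = None,
) -> np.ndarray:
    """(x - min)/(max - min), optionally inverted; NaN passes through.

    Explicit domain bounds support pooled-across-years normalisation; values
    outside the domain are clipped.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        raise ValueError("no finite values to normalise")
    lo = float(finite.min()) if domain_min is None else domain_min
    hi = float(finite.max()) if domain_max is None else domain_max
    if not hi > lo:
        raise ValueError("degenerate domain: max must exceed min")
    out = np.clip((x - lo) / (hi - lo), 0.0, 1.0)
    return 1.0 - out if invert else out


def compute_ev(unit_mean_ndvi: np.ndarray, **norm_kwargs) -> np.ndarray:
    """Vigour: min-max normalised per-unit mean NDVI."""
    return minmax_normalize(unit_mean_ndvi, **norm_kwargs)


def normalize_metrics(
    raw: pd.DataFrame,
    domains: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Normalise each landscape metric to [0, 1], inverting the
    fragmentation densities (higher fragmentation = worse organisation)."""
    out = {}
    for m in METRIC_NAMES:
        lo, hi = (domains or {}).get(m, (None, None))
        out[m] = minmax_normalize(
            raw[m].to_numpy(), invert=m in INVERTED_METRICS,
            domain_min=lo, domain_max=hi)
    return pd.DataFrame(out, index=raw.index)


def compute_eo(
    normalised: pd.DataFrame,
    weights: dict[str, float] | None = None,
) -> np.ndarray:
    """Organisation: weighted sum of the eight normalised metrics."""
    weights = dict(DEFAULT_EO_WEIGHTS if weights is None else weights)
    missing = [m for m in METRIC_NAMES if m not in weights]
    if missing:
        raise KeyError(f"EO weights missing metrics: {missing}")
    if abs(sum(weights[m] for m in METRIC_NAMES) - 1.0) > 1e-9:
        raise ValueError("EO weights must sum to 1")
    W = np.array([weights[m] for m in METRIC_NAMES])
    return normalised[list(METRIC_NAMES)].to_numpy() @ W


def compute_er(
    shares: pd.DataFrame,
    coeffs: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """Resilience: 0.4 * sum A_i * C_resist_i + 0.6 * sum A_i * C_resil_i."""
    coeffs = dict(DEFAULT_RESILIENCE if coeffs is None else coeffs)
    missing = [c for c in _CLASS_COLS if c not in coeffs]
    if missing:
        raise KeyError(f"resilience coefficients missing classes: {missing}")
    for c in _CLASS_COLS:
        lo, hi = coeffs[c]
        if not (0 <= lo <= 1 and 0 <= hi <= 1):
            raise ValueError("coefficients must lie in [0, 1]")
    A = shares[_CLASS_COLS].to_numpy(dtype=float)
    resist = np.array([coeffs[c][0] for c in _CLASS_COLS])
    resil = np.array([coeffs[c][1] for c in _CLASS_COLS])
    return 0.4 * (A @ resist) + 0.6 * (A @ resil)


def compute_ph(ev, eo, er) -> np.ndarray:
    """Natural health index: cube root of EV * EO * ER."""
    ev, eo, er = (np.asarray(a, dtype=float) for a in (ev, eo, er))
    for a in (ev, eo, er):
        if np.any(a[np.isfinite(a)] < 0):
            raise ValueError("PH components must be non-negative")
    return np.cbrt(ev * eo * er)


def compute_hi(ph, cesi) -> np.ndarray:
    """Overall health index: sqrt(PH * CESI)."""
    ph, cesi = np.asarray(ph, dtype=float), np.asarray(cesi, dtype=float)
    if np.any(ph[np.isfinite(ph)] < 0) or np.any(cesi[np.isfinite(cesi)] < 0):
        raise ValueError("HI components must be non-negative")
    return np.sqrt(ph * cesi)


# ---------------------------------------------------------------------------
# Fisher-Jenks natural breaks (exact dynamic programme)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _jenks_dp(sorted_vals, k):  # pragma: no cover - exercised via wrapper
    n = sorted_vals.shape[0]
    pref = np.zeros(n + 1)
    pref2 = np.zeros(n + 1)
    for i in range(n):
        pref[i + 1] = pref[i] + sorted_vals[i]
        pref2[i + 1] = pref2[i] + sorted_vals[i] * sorted_vals[i]

    # cost of segment [i, j] inclusive, 0-based
    def sse(i, j):
        s = pref[j + 1] - pref[i]
        s2 = pref2[j + 1] - pref2[i]
        cnt = j - i + 1
        return s2 - s * s / cnt

    prev = np.empty(n)
    cur = np.empty(n)
    back = np.zeros((k, n), dtype=np.int64)
    for j in range(n):
        prev[j] = sse(0, j)
    for c in range(1, k):
        for j in range(n):
            if j < c:
                cur[j] = 0.0
                back[c, j] = j
                continue
            best = np.inf
            arg = c
            for i in range(c, j + 1):
                v = prev[i - 1] + sse(i, j)
                if v < best:
                    best = v
                    arg = i
            cur[j] = best
            back[c, j] = arg
        prev, cur = cur, prev
    # recover break start-indices
    starts = np.empty(k, dtype=np.int64)
    j = n - 1
    for c in range(k - 1, -1, -1):
        i = back[c, j] if c > 0 else 0
        starts[c] = i
        j = i - 1
    return starts


def jenks_breaks(values: np.ndarray, k: int) -> np.ndarray:
    """Optimal natural breaks: k-1 ascending upper cut values minimising the
    within-class sum of squared deviations (exact Fisher-Jenks DP).

    The cuts are the maxima of the first k-1 classes; classify with
    right-closed intervals.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if k < 2:
        raise ValueError("k must be at least 2")
    if np.unique(x).size < k:
        raise ValueError(f"need at least {k} distinct values for {k} classes")
    s = np.sort(x)
    starts = _jenks_dp(s, k)
    return s[starts[1:] - 1]


def classify(values: np.ndarray, breaks) -> np.ndarray:
    """Assign ordinal classes 1..k by right-closed breaks.

    Class c covers (break_{c-1}, break_c]; the lowest class is closed at the
    data minimum, values above the last break fall in class k. NaN -> 0.
    """
    br = np.asarray(breaks, dtype=float)
    if br.ndim != 1 or np.any(np.diff(br) <= 0):
        raise ValueError("breaks must be strictly ascending")
    x = np.asarray(values, dtype=float)
    out = np.searchsorted(br, x, side="left") + 1
    out = np.where(np.isnan(x), 0, out)
    return out.astype(np.int64)
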