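"""Ecosystem-service value per unit: total ESV, area-specific AESV and the
min-max normalised comprehensive index CESI."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import LANDUSE_NAMES

#: Illustrative per-class service-value coefficients (value per km^2).
#: Ordering water >> forest > grassland > farmland > bare > construction = 0;
#: any positive affine rescaling leaves CESI unchanged.
DEFAULT_VC = {
    "farmland": 1.0,
    "forestland": 3.0,
    "grassland": 2.0,
    "water": 8.0,
    "construction": 0.0,
    "bare": 0.2,
}

_CLASS_COLS = [LANDUSE_NAMES[c] for c in sorted(LANDUSE_NAMES)]


def compute_esv(
    areas: pd.DataFrame,
    coeffs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """ESV = sum_i U_i * VC_i and AESV = ESV / sum_i U_i per unit.

    ``areas`` holds per-unit class areas (columns = the six class names).
    Units with zero total area yield NaN (flagged missing).
    """
    coeffs = dict(DEFAULT_VC if coeffs is None else coeffs)
    missing = [c for c in _CLASS_COLS if c not in coeffs]
    if missing:
        raise KeyError(f"VC coefficients missing classes: {missing}")
    if any(coeffs[c] < 0 for c in _CLASS_COLS):
        raise ValueError("VC coefficients must be non-negative")
    U = areas[_CLASS_COLS].to_numpy(dtype=float)
    vc = np.array([coeffs[c] for c in _CLASS_COLS])
    esv = U @ vc
    totals = U.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        aesv = np.where(totals > 0, esv / totals, np.nan)
    esv = np.where(totals > 0, esv, np.nan)
    return pd.DataFrame({"ESV": esv, "AESV": aesv}, index=areas.index)


def compute_cesi(
    aesv: pd.Series | np.ndarray,
    domain_min: float | None = None,
    domain_max: float | None = None,
) -> np.ndarray:
    """CESI = (AESV - min)/(max - min), clipped to [0, 1].

    Domain bounds default to the min/max of the supplied values; passing the
    pooled-across-years bounds makes CESI comparable between years.
    """
    x = np.asarray(aesv, dtype=float)
    finite = x[np.isfinite(x)]
    lo = float(np.min(finite)) if domain_min is None else domain_min
    hi = float(np.max(finite)) if domain_max is None else domain_max
    if not hi > lo:
        raise ValueError("degenerate AESV domain: max must exceed min")
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)
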