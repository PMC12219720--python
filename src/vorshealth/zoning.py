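"""Temporal level-change typing and county-level control-zone assignment.

Change types over a level trajectory L_1..L_T (ordinal 1-5) use the deltas
dL_t = L_{t+1} - L_t and their sum S_L. County health classes Ia (highest)
to Va (lowest) come from natural breaks on area-weighted mean HI; type
classes Ib..Vb recode the change types (Ib = continuous rise ... Vb =
continuous decline). The level-type pair maps to one of five control zones
through a 23-entry lookup with two flagged fallbacks covering all 25 pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .indices import classify, jenks_breaks

CHANGE_TYPES = (
    "continuous decline",     # I
    "fluctuating decline",    # II
    "stable",                 # III
    "fluctuating rise",       # IV
    "continuous rise",        # V
)

LEVEL_CLASSES = ("Ia", "IIa", "IIIa", "IVa", "Va")  # Ia = highest health
TYPE_CLASSES = ("Ib", "IIb", "IIIb", "IVb", "Vb")

#: change type -> type class (Ib = continuous rise ... Vb = continuous
#: decline); reversed relative to the I..V change-type numbering so that
#: every zone row's caption matches its combinations
TYPE_CLASS_OF_CHANGE = {
    "continuous rise": "Ib",
    "fluctuating rise": "IIb",
    "stable": "IIIb",
    "fluctuating decline": "IVb",
    "continuous decline": "Vb",
}

ZONES = (
    "emergency control",
    "strict control",
    "dynamic regulation",
    "preventive management",
    "sensitive monitoring",
)

#: 23 published level-type combinations -> control zone. The preventive
#: row's duplicated IIIa entries are read as IIa (typo resolution): the only
#: reading yielding 23 distinct pairs that matches the row's caption.
DEFAULT_ZONE_LOOKUP: dict[tuple[str, str], str] = {
    **{pair: "emergency control" for pair in
       [("IVa", "Vb"), ("Va", "Vb"), ("Va", "IVb"), ("IVa", "IVb")]},
    **{pair: "strict control" for pair in
       [("Va", "IIb"), ("Va", "IIIb"), ("IVa", "Ib"), ("IVa", "IIb"),
        ("IVa", "IIIb")]},
    **{pair: "dynamic regulation" for pair in
       [("IIIa", "Ib"), ("IIIa", "IIb"), ("IIIa", "IIIb"), ("IIIa", "IVb"),
        ("IIIa", "Vb")]},
    **{pair: "preventive management" for pair in
       [("Ia", "IIb"), ("Ia", "IIIb"), ("Ia", "IVb"), ("IIa", "IIb"),
        ("IIa", "IIIb"), ("IIa", "IVb")]},
    **{pair: "sensitive monitoring" for pair in
       [("Ia", "Ib"), ("IIa", "Ib"), ("IIa", "Vb")]},
}

#: the two pairs the published table leaves uncovered; assignments follow
#: the nearest row caption and are flagged in output
FALLBACK_ZONE_LOOKUP: dict[tuple[str, str], str] = {
    ("Ia", "Vb"): "sensitive monitoring",   # high health, drastic change
    ("Va", "Ib"): "strict control",         # low health, improving
}


@dataclass
class ChangeTrajectory:
    levels: np.ndarray
    deltas: np.ndarray
    S_L: int
    change_type: str
    fluctuating_neutral: bool = False


def classify_change_type(levels) -> ChangeTrajectory:
    """Assign one of the five change types to a level trajectory.

    Mixed-sign trajectories with S_L = 0 fall outside the published
    predicates and are typed stable (flagged ``fluctuating_neutral``).
    """
    L = np.asarray(levels, dtype=np.int64)
    if L.size < 2:
        raise ValueError("need at least 2 timepoints")
    if L.min() < 1 or L.max() > 5:
        raise ValueError("levels must be ordinal 1..5")
    d = np.diff(L)
    s = int(d.sum())
    if s < 0:
        ctype = "fluctuating decline" if np.any(d > 0) else "continuous decline"
    elif s > 0:
        ctype = "fluctuating rise" if np.any(d < 0) else "continuous rise"
    else:
        ctype = "stable"
    return ChangeTrajectory(L, d, s, ctype,
                            fluctuating_neutral=(s == 0 and np.any(d != 0)))


def county_scores(
    unit_values: pd.Series,
    unit_county_weights: pd.DataFrame,
) -> pd.Series:
    """Area-weighted mean of a per-unit value per county.

    ``unit_county_weights`` has columns (unit_id, county_id, weight) where
    weight is the cell count of that county inside that unit.
    """
    df = unit_county_weights.merge(
        unit_values.rename("value"), left_on="unit_id", right_index=True)
    df = df[np.isfinite(df["value"])]
    if df.empty:
        raise ValueError("no valid units for any county")
    grouped = df.groupby("county_id")
    out = grouped.apply(
        lambda g: np.average(g["value"], weights=g["weight"]),
        include_groups=False)
    return out.rename("score")


def county_level_class(scores: pd.Series, k: int = 5) -> pd.Series:
    """Class counties Ia (highest score group) .. Va (lowest) by natural
    breaks on the county scores."""
    vals = scores.to_numpy(dtype=float)
    if np.unique(vals[np.isfinite(vals)]).size < k:
        raise ValueError(
            f"need at least {k} distinct county scores for {k} classes; "
            "reduce k or check the county partition")
    breaks = jenks_breaks(vals, k)
    groups = classify(vals, breaks)  # 1 = lowest score group
    labels = np.array(LEVEL_CLASSES)[k - groups]  # highest -> Ia
    return pd.Series(labels, index=scores.index, name="level_class")


def assign_control_zone(
    level_class: str,
    type_class: str,
    lookup: dict[tuple[str, str], str] | None = None,
    fallback: dict[tuple[str, str], str] | None = None,
) -> tuple[str, bool]:
    """Zone for a (level, type) pair; returns (zone, fallback_fired)."""
    if level_class not in LEVEL_CLASSES or type_class not in TYPE_CLASSES:
        raise ValueError(f"invalid classes ({level_class}, {type_class})")
    lookup = DEFAULT_ZONE_LOOKUP if lookup is None else lookup
    fallback = FALLBACK_ZONE_LOOKUP if fallback is None else fallback
    _validate_lookup(lookup)
    pair = (level_class, type_class)
    if pair in lookup:
        return lookup[pair], False
    if pair in fallback:
        return fallback[pair], True
    raise KeyError(f"no zone for combination {pair}")


def _validate_lookup(lookup: dict[tuple[str, str], str]) -> None:
    for (lc, tc), zone in lookup.items():
        if lc not in LEVEL_CLASSES or tc not in TYPE_CLASSES:
            raise ValueError(f"malformed lookup key ({lc}, {tc})")
        if zone not in ZONES:
            raise ValueError(f"unknown zone {zone!r}")


def county_zoning(
    unit_hi_by_year: pd.DataFrame,
    unit_levels_by_year: pd.DataFrame,
    unit_county_weights: pd.DataFrame,
    lookup: dict[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Full county table: score, level class, change type, type class, zone.

    Current health uses the final year's HI; the change trajectory uses the
    county-level health level of every year (area-weighted mean HI classed
    on pooled county-score natural breaks).
    """
    years = list(unit_hi_by_year.columns)
    scores = {y: county_scores(unit_hi_by_year[y], unit_county_weights)
              for y in years}
    pooled = np.concatenate([s.to_numpy() for s in scores.values()])
    breaks = jenks_breaks(pooled, 5)
    county_levels = pd.DataFrame({
        y: classify(scores[y].to_numpy(), breaks) for y in years
    }, index=scores[years[0]].index)

    rows = []
    final = scores[years[-1]]
    level_cls = county_level_class(final)
    for cid in final.index:
        traj = classify_change_type(county_levels.loc[cid].to_numpy())
        tclass = TYPE_CLASS_OF_CHANGE[traj.change_type]
        zone, fb = assign_control_zone(level_cls[cid], tclass, lookup)
        rows.append({
            "county_id": cid,
            "score": final[cid],
            "level_class": level_cls[cid],
            "change_type": traj.change_type,
            "type_class": tclass,
            "zone": zone,
            "fallback": fb,
        })
    return pd.DataFrame(rows).set_index("county_id")
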