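"""Config-driven orchestration of the full assessment over T timepoints.

Stages: scenario ingestion (synthetic or rasters on disk) -> tessellation ->
landscape metrics -> indices (EV/EO/ER/PH/AESV/CESI/HI) -> five-level
classification -> spatial statistics -> driver detection -> change typing ->
county zoning. All normalisation domains are pooled across years by default
so indices are temporally comparable. Re-running a config reproduces every
output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import esv, geodetector, indices, landscape, spatial, synthetic, zoning
from .grids import (AssessmentGrid, ContinuousGrid, Grid, LandUseGrid,
                    class_proportions, read_raster, tessellate, write_raster,
                    zonal_stat)

log = logging.getLogger("vorshealth")

DEFAULT_YEARS = (2005, 2010, 2015, 2020, 2022)


@dataclass
class RunConfig:
    seed: int = 0
    shape: tuple[int, int] = (200, 200)
    cell_size_km: float = 1.0
    unit_km: float = 3.0
    n_counties: int = 64
    years: tuple[int, ...] = DEFAULT_YEARS
    input_dir: str | None = None       # read rasters instead of simulating
    normalisation: str = "pooled"      # or "per-year"
    connectivity: int = 8
    eo_weights: dict = field(
        default_factory=lambda: dict(landscape.DEFAULT_EO_WEIGHTS))
    vc_coefficients: dict = field(
        default_factory=lambda: dict(esv.DEFAULT_VC))
    resilience_coefficients: dict = field(
        default_factory=lambda: {
            k: list(v) for k, v in indices.DEFAULT_RESILIENCE.items()})
    level_method: str = "jenks"        # or "fixed" (published HI breaks)
    weights_scheme: str = "queen"
    geodetector_k: int = 5
    geodetector_method: str = "jenks"
    interaction_tol: float = 1e-6
    designed_q: dict = field(
        default_factory=lambda: dict(synthetic.DEFAULT_DESIGNED_Q))
    out_dir: str = "results"

    REQUIRED_TABLES = ("eo_weights", "vc_coefficients",
                       "resilience_coefficients")

    def validate(self) -> None:
        for name in self.REQUIRED_TABLES:
            table = getattr(self, name)
            if not table:
                raise ValueError(f"config missing required table {name!r}")
        if self.normalisation not in ("pooled", "per-year"):
            raise ValueError("normalisation must be 'pooled' or 'per-year'")
        if len(self.years) < 2:
            raise ValueError("need at least 2 timepoints")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.shape, list):
            cfg.shape = tuple(cfg.shape)
        if isinstance(cfg.years, list):
            cfg.years = tuple(cfg.years)
        return cfg

    def content_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # where results land does not change the analysis
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class ScenarioInputs:
    landuse: list[LandUseGrid]
    ndvi: list[ContinuousGrid]
    drivers: dict[str, ContinuousGrid]
    county_labels: np.ndarray


def _load_inputs(cfg: RunConfig) -> ScenarioInputs:
    if cfg.input_dir is None:
        sc = synthetic.generate_scenario(
            shape=cfg.shape, T=len(cfg.years), n_counties=cfg.n_counties,
            designed_q=cfg.designed_q, seed=cfg.seed,
            cell_size=cfg.cell_size_km, unit_km=cfg.unit_km)
        return ScenarioInputs(sc.landuse_series, sc.ndvi_series,
                              sc.drivers, sc.county_labels)
    root = Path(cfg.input_dir)
    landuse = [read_raster(root / f"landuse_{y}.asc", "landuse")
               for y in cfg.years]
    ndvi = [read_raster(root / f"ndvi_{y}.asc", "continuous")
            for y in cfg.years]
    drivers = {}
    for did in synthetic.DRIVER_IDS:
        p = root / f"driver_{did}.asc"
        if p.exists():
            drivers[did] = read_raster(p, "continuous")
    counties = read_raster(root / "counties.asc", "continuous")
    return ScenarioInputs(landuse, ndvi, drivers,
                          counties.values.astype(np.int64))


def _unit_county_weights(units: AssessmentGrid,
                         county_labels: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({
        "unit_id": units.unit_id.ravel(),
        "county_id": county_labels.ravel(),
    })
    out = (df.value_counts().rename("weight").reset_index()
           .sort_values(["unit_id", "county_id"], ignore_index=True))
    return out


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute every stage and write the output tables.

    Returns a map output-name -> path. Raises with a stage-labelled message
    on failure.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    stage = "ingest"
    try:
        t0 = time.perf_counter()
        inputs = _load_inputs(cfg)
        years = list(cfg.years)
        log.info("stage=%s t=%.2fs", stage, time.perf_counter() - t0)

        stage = "tessellate"
        units = tessellate(inputs.landuse[0], cfg.unit_km)

        stage = "metrics"
        raw_metrics = {y: landscape.unit_metrics(lu, units, cfg.connectivity)
                       for y, lu in zip(years, inputs.landuse)}
        comp = {y: class_proportions(lu, units)
                for y, lu in zip(years, inputs.landuse)}
        ndvi_mean = {y: zonal_stat(g, units, "mean")
                     for y, g in zip(years, inputs.ndvi)}

        stage = "indices"
        cell_area = cfg.cell_size_km**2
        counts = units.unit_index.set_index("unit_id")["cell_count"]
        esv_res = {}
        for y in years:
            areas = comp[y].mul(counts * cell_area, axis=0)
            esv_res[y] = esv.compute_esv(areas, cfg.vc_coefficients)

        pooled = cfg.normalisation == "pooled"

        def domain(values_by_year):
            allv = np.concatenate(
                [np.asarray(v, dtype=float) for v in values_by_year.values()])
            allv = allv[np.isfinite(allv)]
            return float(allv.min()), float(allv.max())

        metric_domains = None
        if pooled:
            metric_domains = {
                m: domain({y: raw_metrics[y][m] for y in years})
                for m in landscape.METRIC_NAMES}
            ev_lo, ev_hi = domain(ndvi_mean)
            aesv_lo, aesv_hi = domain(
                {y: esv_res[y]["AESV"] for y in years})

        indicator_rows = []
        metric_rows = []
        resil = {k: tuple(v)
                 for k, v in cfg.resilience_coefficients.items()}
        for y in years:
            norm = indices.normalize_metrics(raw_metrics[y], metric_domains)
            eo = indices.compute_eo(norm, cfg.eo_weights)
            ev = indices.compute_ev(
                ndvi_mean[y].to_numpy(),
                domain_min=ev_lo if pooled else None,
                domain_max=ev_hi if pooled else None)
            er = indices.compute_er(comp[y], resil)
            ph = indices.compute_ph(ev, eo, er)
            cesi = esv.compute_cesi(
                esv_res[y]["AESV"],
                domain_min=aesv_lo if pooled else None,
                domain_max=aesv_hi if pooled else None)
            hi = indices.compute_hi(ph, cesi)
            indicator_rows.append(pd.DataFrame({
                "unit_id": units.unit_ids(), "year": y,
                "EV": ev, "EO": eo, "ER": er, "PH": ph,
                "AESV": esv_res[y]["AESV"].to_numpy(),
                "CESI": cesi, "HI": hi,
            }))
            long = raw_metrics[y].reset_index().melt(
                id_vars="unit_id", var_name="metric", value_name="raw_value")
            nlong = norm.reset_index().melt(
                id_vars="unit_id", var_name="metric",
                value_name="normalised_value")
            long = long.merge(nlong, on=["unit_id", "metric"])
            long.insert(1, "year", y)
            metric_rows.append(long)
        ind = pd.concat(indicator_rows, ignore_index=True)

        stage = "classify"
        if cfg.level_method == "fixed":
            breaks = np.asarray(indices.FIXED_HI_BREAKS)
        else:
            breaks = indices.jenks_breaks(ind["HI"].to_numpy(), 5)
        ind["level"] = indices.classify(ind["HI"].to_numpy(), breaks)

        stage = "spatial"
        weights = spatial.build_weights(
            units.n_unit_rows, units.n_unit_cols, cfg.weights_scheme)
        moran_rows, gi_cols = [], {}
        for y in years:
            sub = ind[ind["year"] == y]
            for var in ("PH", "CESI", "HI"):
                vals = sub[var].to_numpy()
                res = spatial.morans_i(vals, weights)
                moran_rows.append({"year": y, "variable": var, "I": res.I,
                                   "z": res.z, "p": res.p})
            giz = spatial.getis_ord_gstar(sub["HI"].to_numpy(), weights)
            gi_cols[y] = (giz, spatial.classify_hotspots(giz))
        ind["gi_z"] = np.concatenate([gi_cols[y][0] for y in years])
        ind["hotspot"] = np.concatenate([gi_cols[y][1] for y in years])
        moran = pd.DataFrame(moran_rows)

        stage = "geodetector"
        driver_units = {
            did: zonal_stat(g, units, "mean").to_numpy()
            for did, g in inputs.drivers.items()}
        strata = {did: geodetector.discretize(
            v, k=cfg.geodetector_k, method=cfg.geodetector_method)
            for did, v in driver_units.items()}
        fac_rows, int_rows = [], []
        for y in years:
            yv = ind.loc[ind["year"] == y, "HI"].to_numpy()
            qs = {}
            for did in strata:
                res = geodetector.factor_q(yv, strata[did])
                qs[did] = res.q
                fac_rows.append({
                    "year": y, "driver": did, "q": res.q, "p": res.p,
                    "stars": geodetector.significance_stars(res.p)})
            names = sorted(strata)
            for i, a in enumerate(names):
                for b in names[i + 1:]:
                    q12 = geodetector.interaction_q(
                        yv, strata[a], strata[b]).q
                    int_rows.append({
                        "year": y, "driver1": a, "driver2": b,
                        "q1": qs[a], "q2": qs[b], "q12": q12,
                        "type": geodetector.classify_interaction(
                            qs[a], qs[b], q12, cfg.interaction_tol)})
        factors = pd.DataFrame(fac_rows)
        interactions = pd.DataFrame(int_rows)

        stage = "change-typing"
        levels_wide = ind.pivot(index="unit_id", columns="year",
                                values="level")
        ctypes = [zoning.classify_change_type(row).change_type
                  for row in levels_wide.to_numpy()]
        change = levels_wide.copy()
        change.columns = [f"level_{y}" for y in years]
        change["change_type"] = ctypes

        stage = "zoning"
        hi_wide = ind.pivot(index="unit_id", columns="year", values="HI")
        ucw = _unit_county_weights(units, inputs.county_labels)
        zones = zoning.county_zoning(hi_wide, levels_wide, ucw)

        stage = "write"
        float_fmt = "%.17g"  # exact float round-trip

        def save(name, df, index=False):
            p = out / f"{name}.csv"
            df.to_csv(p, index=index, float_format=float_fmt)
            paths[name] = p

        save("indicators", ind)
        save("metrics", pd.concat(metric_rows, ignore_index=True))
        save("moran", moran)
        save("geodetector_factors", factors)
        save("geodetector_interactions", interactions)
        save("change_types", change, index=True)
        save("zoning", zones, index=True)

        # per-unit HI and level rasters for the final year
        y = years[-1]
        sub = ind[ind["year"] == y].set_index("unit_id")
        hi_grid = sub["HI"].to_numpy().reshape(
            units.n_unit_rows, units.n_unit_cols)
        lv_grid = sub["level"].to_numpy().astype(np.int64).reshape(
            units.n_unit_rows, units.n_unit_cols)
        paths["hi_raster"] = write_raster(
            ContinuousGrid(hi_grid, cfg.unit_km), out / f"hi_{y}.asc")
        paths["level_raster"] = write_raster(
            Grid(lv_grid, cfg.unit_km), out / f"level_{y}.asc")

        manifest = {
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "years": years,
            "n_units": int(units.n_units),
            "level_breaks": [float(b) for b in breaks],
            "hi_column_hash": hashlib.sha256(
                ind["HI"].to_numpy().tobytes()).hexdigest(),
            "stages": ["ingest", "tessellate", "metrics", "indices",
                       "classify", "spatial", "geodetector",
                       "change-typing", "zoning"],
        }
        mp = out / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = mp
        return paths
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
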