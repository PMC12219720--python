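# vorshealth

Grid-based ecosystem-health assessment toolkit. Builds per-unit composite
health indices from categorical land-cover and NDVI rasters under the
vigour–organisation–resilience–services (VORS) scheme, then analyses their
spatial structure and drivers, and derives county-level management zones:

- **grids** — ESRI ASCII raster I/O, k×k km block tessellation into
  assessment units, zonal statistics and per-unit land-cover composition.
- **landscape** — eight per-unit landscape metrics (SHDI, AWMPFD, patch
  density fragmentation, contagion, water/forest fragmentation and
  cohesion), FRAGSTATS definitions, per-unit windows.
- **esv** — ecosystem-service value (per-class coefficients × areas),
  area-specific value, and its min–max normalised index (CESI).
- **indices** — EV/EO/ER components, PH = (EV·EO·ER)^(1/3),
  HI = √(PH·CESI), exact Fisher–Jenks natural breaks and five-level
  classification (plus the fixed published HI breakpoints).
- **spatial** — global Moran's I (analytic randomisation z/p and seeded
  permutation option) and Getis-Ord Gi* hot/cold-spot classes on the unit
  lattice.
- **geodetector** — stratified-variance q statistic with noncentral-F
  significance, pairwise interaction detection and the five-way interaction
  taxonomy.
- **zoning** — temporal level-change typing (continuous/fluctuating
  rise/decline, stable), county-level health classes Ia–Va, and the
  23-combination level–type control-zone lookup with two flagged fallbacks.
- **synthetic** — fully seeded scenario generator (latent-Gaussian land
  cover with exact class proportions, clustered transitions, cover-linked
  NDVI with a planted hotspot, drivers with *exactly* designed q values,
  Voronoi county partition) so every stage is testable without real data.
- **pipeline / cli** — config-driven orchestration of all stages with
  byte-reproducible outputs.

## Tests

```sh
python -m pytest -q tests/
```

Unit tests verify each module against independent brute-force oracles
(flood-fill patch labelling, exhaustive natural-breaks enumeration,
double-loop Moran's I / Gi*, direct variance decomposition);
`tests/test_acceptance.py` holds one test per acceptance criterion.

## CLI

```sh
# run the full pipeline on the default synthetic scene (200×200 cells,
# 3×3 km units, 5 timepoints, 64 counties)
vorshealth run-all --seed 1 --out results/

# write the synthetic rasters to disk, then analyse them from files
vorshealth simulate --seed 1 --out scene/
vorshealth run-all --config cfg.yaml   # cfg.yaml: input_dir: scene/
```

Outputs: `indicators.csv` (per unit/year: EV, EO, ER, PH, AESV, CESI, HI,
level, Gi* z, hotspot class), `metrics.csv`, `moran.csv`,
`geodetector_factors.csv`, `geodetector_interactions.csv`,
`change_types.csv`, `zoning.csv`, per-unit HI/level ASCII rasters and a
`manifest.json` recording the config hash, seed and level breaks.

All configuration (coefficient tables, EO weights, normalisation domain,
contiguity scheme, discretisation, zone lookup) lives in a YAML file; see
`vorshealth.pipeline.RunConfig` for keys and defaults.

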