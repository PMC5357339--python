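# sdmrisk

Presence-only maximum-entropy habitat-suitability modelling with
quartile-threshold risk-area change under climate scenarios — a tested,
reusable pipeline exercised end-to-end on synthetic climate and occurrence
data with known ground truth.

The pipeline covers:

- **Synthetic data** (`sdmrisk.synthetic`): seeded, spatially autocorrelated
  monthly climate and elevation rasters on an equal-area grid, a known
  logistic suitability surface over the derived predictors, presence records
  sampled proportional to suitability, and injected record errors (off-grid
  points, elevation mismatches, in-cell duplicates).
- **Preprocessing** (`sdmrisk.preprocess`): occurrence cleaning in a fixed
  order (off-grid removal → elevation-mismatch filter with a strict 100 m
  tolerance → one-record-per-cell deduplication, with a reconciling count
  report) and the three bioclimatic predictors: growing degree days (GDD,
  base 5 °C), absolute minimum temperature of the coldest month, and annual
  water balance (precipitation − Thornthwaite potential evapotranspiration).
- **Maximum-entropy model** (`sdmrisk.maxent`): linear/quadratic/product/
  hinge feature expansion scaled to the background, ℓ1-penalized fitting by
  accelerated proximal gradient with a KKT stopping rule, raw and
  entropy-calibrated logistic outputs, AICc-based settings tuning over
  feature classes × regularization multipliers, replicate fitting with
  75/25 splits, and response curves.
- **Evaluation** (`sdmrisk.evaluation`): rank-based AUC against background
  pseudo-absences, jackknife variable importance from single-variable
  training gains (normalized to sum to one), and multivariate environmental
  similarity surfaces flagging extrapolation.
- **Risk change** (`sdmrisk.risk`): the top-quartile threshold of present-day
  suitability, binary reclassification of current and scenario maps with
  that single threshold, areas in km², and both printed change conventions
  (percent increase and future-as-percent-of-current).
- **I/O + CLI** (`sdmrisk.io`, `sdmrisk.cli`, `sdmrisk.pipeline`): text
  ASCII-grid rasters (float32-exact round trip), Darwin-Core-like occurrence
  CSVs, JSON reports, and a deterministic end-to-end runner with a manifest
  of seeds, counts and output digests.

## CLI

Each stage is independently invocable:

```sh
sdmrisk simulate --rows 60 --cols 120 --seed 1 --n 500 --outdir out/sim
sdmrisk clean --occurrences out/sim/occurrences.csv --dem out/sim/elevation.asc \
    --out out/clean.csv --report out/cleaning.json
sdmrisk fit --occurrences out/clean.csv --bioclim-dir out/sim --replicates 15 \
    --seed 1 --outdir out/fit
sdmrisk har --suitability out/fit/suitability.asc \
    --scenario rcp60 out/rcp60.asc --out out/har.json
sdmrisk run-all --config config.json --seed 1 --outdir out/run
```

`run-all` accepts a JSON config (grid size, training/projection regions,
scenario warming/precipitation parameters, feature classes, regularization,
replicates, cleaning tolerance, cell area, master seed); every field has a
default, and flags override the file.

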