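# prioritygrid

Two-level spatial conservation prioritization on nested grids: ensemble
habitat-suitability modeling from presence-only records, binary range
construction, richness / irreplaceability / complementarity mapping, reserve
gap analysis with range-scaled targets, and cross-resolution congruence
statistics — exercised end-to-end on synthetic landscapes with known ground
truth.

## What it does

- **`synthetic_landscape`** (`prioritygrid.synthetic`) — deterministic
  synthetic worlds: spatially autocorrelated continuous predictors plus one
  categorical land-cover layer, species whose true suitability is a logistic
  function of the predictors, presence-only records sampled inside true
  ranges, and rectangular reserves of known total area, on two nested grids
  (coarse cell = k × k fine cells).
- **`predictor_prep`** (`prioritygrid.predictors`) — block aggregation to a
  coarse grid (mean for continuous layers, modal class for land cover) and
  iterative variance-inflation-factor screening (drop largest VIF until all
  are below 5).
- **`ensemble_sdm`** (`prioritygrid.sdm`) — pseudo-absence sampling,
  10-fold cross-validated AUC per learner (logistic / boosted trees /
  random forest), an AUC-weighted consensus restricted to learners with
  AUC > 0.7, a commission-minimizing binarization threshold (max over
  sensitivity-floor, accuracy, kappa and TSS criteria), record-cell
  override, and barrier clipping of suitable patches isolated from the
  records by more than the mean nearest-neighbour record distance.
  Single-record species bypass modeling: their range is the occupied cell.
- **`priority_mapping`** (`prioritygrid.priority`) — species richness and
  the definitional irreplaceability ratio (combinations of cells that meet
  all targets and fail without the focal cell, over all meeting
  combinations): exact enumeration up to 20 cells, a uniform Bernoulli(1/2)
  subset sampler with standard errors, and a forced-cell-reduction +
  importance-sampling estimator for large instances. Conservation value
  (nothing protected) and complementarity (reserves credited, protected
  cells masked) are layers over one grid.
- **`reserve_gap`** (`prioritygrid.gap`) — polygon→cell coverage fractions
  by exact geometric intersection, the area-matching coverage threshold
  (protected ⇔ coverage strictly greater), log-linear range-scaled targets
  (100% of cells for the smallest range down to 5% for the largest), and
  met / partial gap / total gap classification.
- **`cross_scale`** (`prioritygrid.crossscale`) — Pearson correlations
  tested against one-sided Monte-Carlo permutation nulls, arcsine-transformed
  percentages, best-1% priority envelopes, and nestedness of fine envelopes
  within coarse ones.
- **`workflow_cli`** (`prioritygrid.pipeline`, `prioritygrid.cli`) — YAML
  config, validation, a fully seeded end-to-end run, and a manifest of
  output digests (identical seeds give bit-identical outputs).

## CLI

```sh
# generate a synthetic world (predictors .asc, records.csv, reserves.geojson)
prioritygrid synth --seed 3 --out world/ --rows 48 --cols 48 --species 5

# full two-level analysis from a config
prioritygrid run --config run.yaml --out out/

# gap analysis from stored range grids + reserves
prioritygrid gap --ranges out/fine --reserves world/reserves.geojson

# cross-scale congruence for one priority index
prioritygrid crossscale --coarse out/coarse --fine out/fine --index richness
```

A minimal `run.yaml` (all omitted keys take the documented defaults —
500/200 pseudo-absences, AUC cutoff 0.7, sensitivity floor 0.9, targets
100%/5%, 1% envelopes, 30000 permutations):

```yaml
seed: 7
synthetic:
  fine: {origin_lon: 0.0, origin_lat: 6.0, cell_size: 0.1, n_rows: 60, n_cols: 60}
  nesting_factor: 5
  n_species: 5
  n_predictors: 4
  records_per_species: 40
  reserve_fraction: 0.1
sdm:
  pseudo_absences_coarse: 100   # must fit the coarse grid
priority:
  n_samples: 10000
```

Outputs per level: `richness.asc`, `conservation_value.asc`,
`complementarity.asc`, `range_<species>.asc`, `model_report.csv`,
`gap_report.csv`; plus `cross_scale_correlations.csv`,
`cross_scale_nestedness.csv`, `cross_scale_summary.txt` and
`manifest.json` at the top level.

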