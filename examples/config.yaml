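# Full-pipeline configuration for `geoxai run examples/config.yaml`.
# Every field is optional; defaults shown here. Artifacts (counties.csv,
# weights.gal, q_table.csv, eval_report.csv, importance.csv, profiles.csv,
# breakdown.json, attributions.csv, map.geojson, manifest.json) land in outdir.
seed: 7
outdir: runs/demo
lattice:
  nrows: 20
  ncols: 20
  cell_size: 1.0
simulate:
  spatial_range: 4.0     # Gaussian smoothing scale of the covariate fields, in cells
weights:
  rule: queen            # rook | queen; set `band: 1.5` for a distance band instead
split:
  fractions: [0.70, 0.15, 0.15]
train:
  grids: small           # small | default hyperparameter grids
  folds: 5
  mode: all_models       # all_models | best_of_family
explain:
  n_repeats: 5           # permutation-importance repeats
  top_features: 6        # factors profiled and mapped
  profile_points: 21
  al_intervals: 10
  n_ref: 200             # reference subsample for break-down expectations
  lmi_factor: smoking
  lmi_permutations: 199
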