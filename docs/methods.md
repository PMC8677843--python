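# Methods

This note records the models, estimators, defaults and design choices behind
`geoxai`, and what the synthetic testbed does and does not establish.

## The synthetic county testbed

The pipeline is designed for observational county data (a mortality rate per
100,000 joined to behavioural, socioeconomic, demographic, pollution and
terrain covariates).  Such data cannot be bundled, so every stage is
exercised on a generated stand-in with known ground truth.

**Geometry.** A regular `nrows × ncols` lattice of unit cells ("counties"),
default 40×40 (n = 1600) for benchmarks and 20–30 per side for cheaper runs.
Problem sizes in the tests are the package's standard benchmark sizes and
are stated with each test.

**Covariates.** Each continuous covariate is an independent Gaussian white
-noise field smoothed with a Gaussian kernel of scale `spatial_range`
(default 4 cells) and affinely rescaled to a realistic range (smoking
10–40%, poverty 5–45%, elevation 0–3000 m, PM2.5 4–15 µg/m³, …).  Smoothing
was chosen over SAR/CAR simulation because it is simple, its single
parameter maps monotonically to Moran's I (≈0 at range 0, >0.5 at range ≥10
cells on a 40×40 lattice), and it is directly checkable with a brute-force
Moran oracle.  Categorical covariates (radon zone 1–3, urban–rural 1–4,
coal 0/1) threshold an auxiliary smoothed field at quantiles, so all levels
appear with near-equal frequency on maps ≥20×20.

**Response.** `response = intercept + Σ additive effects + Σ interactions +
categorical offsets + N(0, noise_sd)`, with the noiseless surface stored in
`response_true` and the full `EffectSpec` attached to the table.  The
default surface has positive effects of smoking (+1.5 per %), poverty
(+0.3), PM2.5 (+0.8) and % white (+0.08); negative effects of elevation
(−0.004 per m) and % Hispanic (−0.15); a hinge interaction
`0.05 · max(0, smoking − 30) · poverty` (poverty only matters above 30%
smoking); small offsets for radon zone, urban–rural class and coal; and
noise σ = 8 per 100,000.  With intercept 15 the mean rate is ≈63 per
100,000 and the attainable test R² ≈ 0.6–0.75 — the regime of real
county-level mortality models.  No clipping at zero by default (the default
surface keeps rates positive with overwhelming margin), so additivity
checks stay exact; a clip option exists and is off.

A second named surface, `nonlinear_effect_spec()` (hinge smoking effect at
25%, strong smoking×poverty interaction, σ = 4), is used for
model-comparison benchmarks where the question is whether flexible learners
beat (locally) linear spatial regressions; on the default mostly-linear
surface GW-OLS is close to optimal and that comparison is uninformative.

**What passing tests show.** Recovery results on this testbed demonstrate
the *mechanics* (honest stacking, correct explainer algebra, correct
spatial statistics) under independent smooth covariates and additive noise.
Real county data add correlated covariates, spatially structured residuals,
measurement error and suppression-driven missingness; none of those are
emulated, so test results here do not certify performance on real data.

## Spatial statistics

* **Gi\*** uses binary weights **with** self included (the "star"
  convention); the denominator uses the population standard deviation.
  A constant field returns all z = 0 with a warning.  Bin thresholds are
  the classical two-sided 90/95/99% cutoffs (1.645/1.960/2.576) without
  false-discovery-rate correction; weights default to queen contiguity
  (distance-band is available) — both stated as package defaults, since
  different GIS tools make different choices here.
* **Bivariate local Moran** uses row-standardized weights **without** self;
  variables are z-scored with the population SD.  Inference is by
  conditional permutation (hold unit i fixed, permute the other n−1 values
  over its neighbors; default 999 permutations, seeded), p = (#{|I_perm| ≥
  |I_obs|}+1)/(n_perm+1), so 1/(n_perm+1) is the attainable floor.  Cluster
  labels HH/HL/LH/LL from the signs of z_x and the lag, `ns` above alpha.
* **q-statistic** is computed in sum-of-squares form q = 1 − SSW/SST, which
  sidesteps the sample-vs-population variance ambiguity.  Significance uses
  the geodetector noncentral-F test, F = ((N−L)/(L−1))·q/(1−q) against
  F(L−1, N−L; λ).  The textbook λ formula with raw strata means is
  location-variant (a large overall mean inflates λ without bound and
  drives p to 1 for any factor); since q and F are location-invariant, λ is
  evaluated on the mean-centered variable, making it ≈ SSB/σ².  This test
  is deliberately conservative for weak factors — a near-zero q can carry a
  large p even at n in the thousands.  Continuous factors are stratified by
  quantiles (k = 5 default; right-closed bins, boundary ties to the lower
  stratum); categorical factors are used as-is.

## Split

Stratified 70/15/15 split with the seven Gi\* bins as strata.  Per-stratum
counts come from largest-remainder rounding (deterministic, each partition
within one unit of the exact fractional allocation), membership from a
seeded shuffle.  Strata smaller than three units go entirely to train with
a warning.

## Learners and stacking

Five families: penalized linear (ridge/elastic-net), random forest,
gradient boosting, XGBoost, multilayer perceptron (3×100 tanh default
card; optional, off in the reduced grids).  Hyperparameters are tuned by
random grid search: up to `budget` combinations sampled without
replacement, each scored by pooled K-fold CV RMSE on one shared, seeded
fold assignment (default tenfold; the reduced benchmark grids use 3–5
folds).  Early stopping on tree additions uses the native mechanisms of
each library (sklearn GB: `n_iter_no_change=2, tol=0.001` on an internal
validation fraction; XGBoost: `early_stopping_rounds=2` on the CV
validation fold), recorded in each model card as (tolerance 0.001,
rounds 2); random forests are not sequential, so no stopping applies.

Default grids are seeded with the best published settings for this class of
problem (RF 576 trees / depth 30 / sample rate 0.6; GBM 500 / 0.5 / 20 / 1;
XGB 350 / 3 / 50 / 0.75; ridge GLM with unit penalty) plus neighbors; they
are starting points, not asserted optima for synthetic data.

Stacking: out-of-fold predictions from a clone of each candidate (entry
(i, l) never comes from a model that saw row i) form the meta-feature
matrix; the meta-learner is ridge-regularized least squares with a tiny
penalty (1e-6) — enough to absorb exactly collinear meta-features without
materially changing the fit — with an optional non-negative-weights variant
(bounded least squares).  `all_models` stacks every candidate,
`best_of_family` the best CV-RMSE candidate per family.  Candidates are
already refitted on the full training partition during tuning, so the
deployed stack is intercept + Σ coef·base(x) over full-data fits.

## Evaluation

MAE and RMSE are the exact formulas; R² is the squared Pearson correlation
of observed vs predicted (invariant to affine recalibration — it measures
association, not calibration).  The bias–variance decomposition refits the
model on seeded bootstrap resamples of the training pool (default ten,
optional `resample_size`) and evaluates on a fixed test set:
Bias² + Var + σ² ≈ mean squared error.  Squared bias — not the unsquared
"Bias + Var + σ" sometimes printed — is the implemented convention, since
only the squared form closes the decomposition.  The plug-in estimator of
squared bias is biased upward by Var/n_resamples; that amount is
subtracted (floored at zero).  When the true surface is unknown, bias is
measured against the observed test responses and flagged
(`truth_known=False`).

## Explainers

All explainers treat the model as a black box (`predict` over a feature
DataFrame) and are pure functions of (model, data, seed).

* **Permutation importance**: per feature, `n_repeats` seeded permutations
  of that column; drop-out loss reported both as ratio (the factor by which
  RMSE increases) and difference, with the Monte-Carlo spread.  Zero
  baseline loss leaves ratios undefined (NaN) with a warning.
* **PD**: grid at empirical quantiles (default 51 points), mean prediction
  with the feature clamped.  **LD**: same, averaging only over the nearest
  `neighborhood_frac` of rows (fraction 1 reduces exactly to PD).
  **AL**: quantile intervals (default 20), per-interval mean prediction
  difference between the interval edges over the rows in the interval,
  cumulative sum, then mean-centered under the empirical interval weights
  (midpoint rule); empty intervals (possible under heavy ties) are merged
  with a warning.  For categorical (integer-coded) features the quantile
  grid collapses to the observed levels; profiles over unordered categories
  should be read as per-level PD.
* **Break-down**: intercept = mean prediction over the reference data
  (optionally a seeded subsample, `n_ref`); contributions by sequential
  conditioning, either in a fixed order or greedily (largest |change in
  expected prediction| first, ties broken lexicographically).  The deltas
  telescope, so intercept + Σ deltas equals the final conditional
  expectation, which — when every model feature is conditioned — *is* the
  model's prediction for the observation; additivity therefore holds to
  floating-point precision for any model.
* **Attribution maps** run break-down for every unit.  Default: one fixed
  ordering for all units (the global permutation-importance ranking when
  the response is supplied), because per-unit greedy orderings make columns
  incomparable across units; greedy mode is retained for single-county
  plots.  The fixed-order path is vectorized (chunked substitution of the
  whole map into the reference data), and the stored `prediction` column is
  computed by the model directly, so the additivity invariant is a real
  check rather than bookkeeping.

## Spatial regression references

Lag (y = ρWy + Xβ + ε) and error (u = λWu + ε) models are fitted by
maximum likelihood with the exact dense log-determinant: log|I − ρW| =
Σ log|1 − ρλᵢ| over the eigenvalues of W.  For row-standardized weights
derived from a symmetric binary matrix, the eigenvalues are computed
symmetrically (D^{-1/2}AD^{-1/2}), which is exact and fast at desk scale
(n ≤ a few thousand); a general eigensolve is the fallback.  The lag
likelihood is concentrated through the residuals of y and Wy on X, so the
ρ search is O(n) per candidate.  Held-out prediction uses the trend
component Xβ̂ only: the autoregressive term requires the joint train+test
weights structure, and the trend is the standard out-of-sample predictor
for these models' role here (a comparison baseline).

GW-OLS fits one weighted least-squares regression per location with
Gaussian kernel weights exp(−d²/(2b²)); the kernel is fixed as Gaussian.
Bandwidth selection is leave-one-out CV RMSE over a geometric grid from
twice the median nearest-neighbor distance to the map extent (CV chosen
over AICc; both are standard).  Fits error out when the effective sample
(Σ weights) at any location falls below the coefficient count; the pipeline
widens the bandwidth geometrically until feasible.

## Pipeline and reproducibility

`run_pipeline` executes simulate → weights → Gi\*/LMI/q → split → tune →
stack → evaluate (base learners, stacks, spatial lag/error, GW-OLS; a
Table-2-style model × partition CSV) → importance/profiles/break-down →
attribution map + GeoJSON, writing every artifact plus a manifest (config
hash, per-stage seeds, per-artifact SHA-256).  Each stage's seed derives
deterministically from the root seed and a stage index, so a saved config
re-runs bit-identically.  The configuration schema is validated up front;
errors name the offending field path.

The library API is the primary interface (with `examples/` as narrative
entry points); the `geoxai` CLI wraps the pipeline (`run`) and the cheap
standalone stages (`simulate`, `weights`, `eda`, `split`).  Training and
explanation stages run inside `run`, where the fitted models live in
memory — serializing models to shuttle them between shell commands would
add surface without value.

## Known limitations

* Covariate fields are generated independently, so the synthetic testbed
  understates the collinearity of real risk factors; AL-vs-PD differences
  are correspondingly mild except in the constructed correlated examples.
* The geodetector noncentral-F p-value is conservative for weak factors;
  rankings by q are the robust output.
* Spatial lag/error out-of-sample prediction is trend-only (see above).
* Greedy break-down orderings are per-unit and not comparable across a map;
  use the fixed ordering for contribution surfaces.
* The multilayer-perceptron family is an ordinary sklearn MLP standing in a
  base-learner slot; no attempt is made to reproduce any specific deep
  architecture's training dynamics beyond the recorded default card.
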