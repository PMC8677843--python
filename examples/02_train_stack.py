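"""Tune base learners and fit the stacked ensemble.

Stratifies the map into train/valid/test with Gi* bins, tunes four base
learner families by random grid search with 5-fold CV, stacks them with a
ridge GLM meta-learner on out-of-fold predictions, and compares test RMSE.
"""

from geoxai import (
    contiguity_weights,
    evaluate,
    fit_stack,
    gi_star,
    make_synthetic_counties,
    oof_predictions,
    stratified_split,
    tune_learners,
)
from geoxai.learners import feature_columns, small_grids

table = make_synthetic_counties(30, 30, seed=42)
w = contiguity_weights(table, "queen", include_self=True)
table["gi_bin"] = gi_star(table["response"], w).gi_bin
split = stratified_split(table, "gi_bin", seed=1)

factors = feature_columns(table)
X, y = table[factors], table["response"].to_numpy()
tr, te = split.mask("train"), split.mask("test")

learners = tune_learners(small_grids(), X[tr], y[tr], folds=5, seed=2)
meta = oof_predictions(learners, X[tr], y[tr], folds=5, seed=2)
stack = fit_stack(learners, meta, y[tr], mode="all_models", feature_names=factors)

print(f"{len(learners)} tuned candidates across "
      f"{len(set(t.family for t in learners))} families\n")
print(f"{'model':<28} {'cv_rmse':>8} {'test_rmse':>10} {'test_r2':>8}")
for t in learners:
    rep = evaluate(y[te], t.predict(X[te]))
    print(f"{t.label:<28} {t.cv_rmse:>8.3f} {rep.rmse:>10.3f} {rep.r2:>8.3f}")
rep = evaluate(y[te], stack.predict(X[te]))
print(f"{'stack (all models)':<28} {'-':>8} {rep.rmse:>10.3f} {rep.r2:>8.3f}")
print("\nThe stack's test RMSE should match or beat every base learner: the "
      "meta-learner reweights them using only honest out-of-fold predictions. "
      "The irreducible noise of the simulated rates is 8 per 100,000, so test "
      "RMSE near 8 means the signal is essentially fully captured.")
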