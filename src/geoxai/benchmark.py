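"""Seeded end-to-end benchmark replicates on synthetic county maps.

One replicate = simulate a map, derive Gi* bins, split stratified 70/15/15,
tune the base learners on the training partition, stack them, and score
everything on the held-out test partition, plus the permutation-importance
ranking of the stack.  Used to measure the recovery properties of the
pipeline (does the stack beat its base learners? is the dominant simulated
risk factor ranked first?) over independent seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .eda import gi_star
from .evaluation import rmse
from .explain import permutation_importance
from .learners import (
    feature_columns,
    fit_stack,
    oof_predictions,
    small_grids,
    tune_learners,
)
from .split import stratified_split
from .synthetic import make_synthetic_counties
from .weights import contiguity_weights

__all__ = ["BenchmarkResult", "stack_benchmark"]


@dataclass
class BenchmarkResult:
    seed: int
    n_units: int
    stack_test_rmse: float
    base_test_rmse: dict[str, float]
    importance_ranking: list[str]
    stack: object
    table: object
    test_mask: np.ndarray

    @property
    def best_base_test_rmse(self) -> float:
        return min(self.base_test_rmse.values())


def stack_benchmark(
    seed: int,
    nrows: int = 40,
    ncols: int = 40,
    folds: int = 3,
    mode: str = "all_models",
    importance_repeats: int = 5,
) -> BenchmarkResult:
    """Run one full simulate-split-tune-stack-explain replicate."""
    table = make_synthetic_counties(nrows, ncols, seed=seed)
    w = contiguity_weights(table, "queen", include_self=True)
    table["gi_bin"] = gi_star(table["response"], w).gi_bin
    assignment = stratified_split(table, "gi_bin", seed=seed + 1)

    factors = feature_columns(table)
    X = table[factors]
    y = table["response"].to_numpy()
    tr = assignment.mask("train")
    te = assignment.mask("test")

    learners = tune_learners(small_grids(), X[tr], y[tr], folds=folds, seed=seed + 2)
    meta = oof_predictions(learners, X[tr], y[tr], folds=folds, seed=seed + 2)
    stack = fit_stack(learners, meta, y[tr], mode=mode, feature_names=factors)

    base_rmse = {t.label: rmse(y[te], t.predict(X[te])) for t in learners}
    stack_rmse = rmse(y[te], stack.predict(X[te]))
    imp = permutation_importance(
        stack, X[te], y[te], n_repeats=importance_repeats, seed=seed + 3
    )
    return BenchmarkResult(
        seed=seed,
        n_units=len(table),
        stack_test_rmse=stack_rmse,
        base_test_rmse=base_rmse,
        importance_ranking=imp.ranking(),
        stack=stack,
        table=table,
        test_mask=te,
    )
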