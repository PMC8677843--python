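"""Base learners, random grid search, and stacked generalization.

Five base-learner families mirror the study design: a penalized linear model
(GLM), random forest, gradient boosting, extreme gradient boosting and a
multilayer perceptron.  Hyperparameters are tuned by random grid search
scored with K-fold cross-validated RMSE (ten folds by default), with early
stopping on the boosting families (stopping tolerance 0.001, stopping rounds
2).  Stacking follows the classic three steps: tune the base learners,
collect their out-of-fold cross-validation predictions as meta-features, and
fit a GLM meta-learner (ridge-regularized least squares) on those
meta-features.  Two ensemble modes exist: ``all_models`` stacks every tuned
candidate, ``best_of_family`` only the best candidate per family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from sklearn.base import clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Ridge
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from xgboost import XGBRegressor

__all__ = [
    "FAMILIES",
    "LearnerSpec",
    "TunedLearner",
    "MetaFeatures",
    "StackModel",
    "default_grids",
    "small_grids",
    "random_grid_search",
    "tune_learners",
    "oof_predictions",
    "fit_stack",
    "feature_columns",
]

FAMILIES = (
    "penalized-linear",
    "random-forest",
    "gradient-boosting",
    "extreme-gradient-boosting",
    "multilayer-perceptron",
)

DEFAULT_EARLY_STOP = (0.001, 2)  # (stopping tolerance, stopping rounds)


@dataclass
class LearnerSpec:
    """One base-learner family with its hyperparameter grid and search budget."""

    family: str
    grid: dict[str, list]
    budget: int = 20
    early_stop: tuple[float, int] = DEFAULT_EARLY_STOP

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be nonempty")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")


@dataclass
class TunedLearner:
    """A scored hyperparameter combination with its full-data fitted estimator."""

    family: str
    params: dict
    cv_rmse: float
    estimator: object
    early_stop: tuple[float, int] = DEFAULT_EARLY_STOP
    label: str = ""

    def card(self) -> dict:
        """Model card: family, chosen hyperparameters, CV score, stopping rule."""
        return {
            "family": self.family,
            "hyperparameters": dict(self.params),
            "cv_rmse": float(self.cv_rmse),
            "early_stop": {
                "stopping_tolerance": self.early_stop[0],
                "stopping_rounds": self.early_stop[1],
            },
        }

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=float)


@dataclass
class MetaFeatures:
    """Out-of-fold base-learner predictions: the meta-learner's design matrix."""

    matrix: np.ndarray  # n_train x n_base
    fold_assignment: np.ndarray
    labels: list[str]

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.labels.index(label)]


@dataclass
class StackModel:
    """Deployed stacked ensemble: prediction = intercept + sum coef_l * base_l(x)."""

    learners: list[TunedLearner]
    intercept: float
    coefs: np.ndarray
    mode: str = "all_models"
    feature_names: list[str] = field(default_factory=list)

    def base_predictions(self, X) -> np.ndarray:
        return np.column_stack([l.predict(X) for l in self.learners])

    def predict(self, X) -> np.ndarray:
        return self.intercept + self.base_predictions(X) @ self.coefs


# --- estimator construction -------------------------------------------------

# Default grids are seeded with the best published hyperparameter settings of
# the study models (random forest 576 trees / depth 30 / sample rate 0.6,
# GBM 500 trees / column sample 0.5 / depth 20 / min rows 1, XGBoost 350
# trees / depth 3 / min child weight 50 / column sample 0.75, ridge GLM with
# unit penalty, 3x100 tanh network) plus neighboring values to search over.


def default_grids() -> list[LearnerSpec]:
    return [
        LearnerSpec("penalized-linear", {"penalty": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.0, 0.5]}),
        LearnerSpec(
            "random-forest",
            {"n_estimators": [200, 576], "max_depth": [10, 30], "max_samples": [0.6, 0.9]},
        ),
        LearnerSpec(
            "gradient-boosting",
            {
                "n_estimators": [200, 500],
                "max_depth": [5, 20],
                "max_features": [0.5, 1.0],
                "min_samples_leaf": [1, 10],
                "learning_rate": [0.05, 0.1],
            },
        ),
        LearnerSpec(
            "extreme-gradient-boosting",
            {
                "n_estimators": [100, 350],
                "max_depth": [3, 6],
                "min_child_weight": [10, 50],
                "colsample_bytree": [0.75, 1.0],
                "learning_rate": [0.05, 0.1],
            },
        ),
        LearnerSpec(
            "multilayer-perceptron",
            {"hidden_layer_sizes": [(100, 100, 100)], "alpha": [1e-5, 1e-3]},
        ),
    ]


def small_grids(include_mlp: bool = False) -> list[LearnerSpec]:
    """Reduced grids sized for desk-scale synthetic runs."""
    specs = [
        LearnerSpec("penalized-linear", {"penalty": [0.1, 1.0], "l1_ratio": [0.0]}),
        LearnerSpec("random-forest", {"n_estimators": [100], "max_depth": [None, 10]}),
        LearnerSpec(
            "gradient-boosting",
            {"n_estimators": [150], "max_depth": [3, 5], "learning_rate": [0.1]},
        ),
        LearnerSpec(
            "extreme-gradient-boosting",
            {"n_estimators": [150], "max_depth": [3, 5], "learning_rate": [0.1]},
        ),
    ]
    if include_mlp:
        specs.append(
            LearnerSpec(
                "multilayer-perceptron",
                {"hidden_layer_sizes": [(50, 50)], "alpha": [1e-4]},
            )
        )
    return specs


def _make_estimator(family: str, params: dict, seed: int, early_stop=None):
    p = dict(params)
    if family == "penalized-linear":
        penalty = p.pop("penalty", 1.0)
        l1_ratio = p.pop("l1_ratio", 0.0)
        if l1_ratio == 0.0:
            return Ridge(alpha=penalty, **p)
        return ElasticNet(alpha=penalty, l1_ratio=l1_ratio, random_state=seed, **p)
    if family == "random-forest":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **p)
    if family == "gradient-boosting":
        kw = dict(p)
        if early_stop is not None:
            tol, rounds = early_stop
            kw.update(n_iter_no_change=rounds, tol=tol, validation_fraction=0.1)
        return GradientBoostingRegressor(random_state=seed, **kw)
    if family == "extreme-gradient-boosting":
        return XGBRegressor(
            random_state=seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
            **p,
        )
    if family == "multilayer-perceptron":
        kw = dict(hidden_layer_sizes=(100, 100, 100), activation="tanh", max_iter=300)
        kw.update(p)
        return MLPRegressor(random_state=seed, **kw)
    raise ValueError(f"unknown learner family {family!r}")


def _fit(est, X, y, eval_set=None, early_stop=None):
    """Fit, wiring up XGBoost early stopping when a scoring set is available."""
    if isinstance(est, XGBRegressor):
        if eval_set is not None and early_stop is not None:
            est.set_params(early_stopping_rounds=early_stop[1])
            est.fit(X, y, eval_set=[eval_set], verbose=False)
        else:
            est.set_params(early_stopping_rounds=None)
            est.fit(X, y)
    else:
        est.fit(X, y)
    return est


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Risk-factor columns of a county table (continuous then categorical)."""
    cont = table.attrs.get("continuous_features")
    cat = table.attrs.get("categorical_features")
    if cont is not None and cat is not None:
        return list(cont) + list(cat)
    skip = {"unit_id", "row", "col", "x", "y", "response", "response_true",
            "partition", "gi_z", "gi_bin", "p_value"}
    return [c for c in table.columns if c not in skip]


# --- tuning and stacking ----------------------------------------------------


def _grid_combinations(grid: dict[str, list]) -> list[dict]:
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def random_grid_search(
    spec: LearnerSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> list[TunedLearner]:
    """Score random hyperparameter combinations by K-fold CV RMSE.

    Samples at most ``spec.budget`` combinations without replacement (the
    full grid if the budget covers it), scores each by pooled out-of-fold
    RMSE on a shared fold assignment, fits the estimator on the full data,
    and returns candidates ordered best-first.
    """
    if folds < 2:
        raise ValueError("need at least 2 CV folds")
    y = np.asarray(y, dtype=float)
    combos = _grid_combinations(spec.grid)
    rng = np.random.default_rng(seed)
    if len(combos) > spec.budget:
        picked = rng.choice(len(combos), size=spec.budget, replace=False)
        combos = [combos[i] for i in sorted(picked)]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    results = []
    for params in combos:
        oof = np.empty(len(y))
        for tr, va in splits:
            est = _make_estimator(spec.family, params, seed, early_stop=spec.early_stop)
            _fit(
                est,
                X.iloc[tr],
                y[tr],
                eval_set=(X.iloc[va], y[va]),
                early_stop=spec.early_stop,
            )
            oof[va] = est.predict(X.iloc[va])
        cv_rmse = float(np.sqrt(np.mean((y - oof) ** 2)))
        full = _make_estimator(spec.family, params, seed, early_stop=spec.early_stop)
        _fit(full, X, y)
        results.append(
            TunedLearner(
                family=spec.family,
                params=params,
                cv_rmse=cv_rmse,
                estimator=full,
                early_stop=spec.early_stop,
            )
        )
    results.sort(key=lambda t: t.cv_rmse)
    for i, t in enumerate(results):
        t.label = f"{t.family}#{i}"
    return results


def tune_learners(
    specs: list[LearnerSpec],
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
) -> list[TunedLearner]:
    """Tune every family on the same fold assignment; flatten all candidates."""
    out: list[TunedLearner] = []
    for spec in specs:
        out.extend(random_grid_search(spec, X, y, folds=folds, seed=seed))
    for i, t in enumerate(out):
        t.label = f"{t.family}#{i}"
    return out


def oof_predictions(
    learners: list[TunedLearner],
    X: pd.DataFrame,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> MetaFeatures:
    """Honest out-of-fold predictions for every learner on shared folds.

    Entry (i, l) comes from a clone of learner l trained on the folds that do
    not contain row i — the no-leakage contract of stacked generalization.
    An explicit per-row ``fold_assignment`` overrides the seeded K-fold split
    (so folds can be shared across calls or permuted with the rows).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if fold_assignment is not None:
        fold_assignment = np.asarray(fold_assignment)
        if len(fold_assignment) != n:
            raise ValueError("fold_assignment length mismatch")
        fold_ids = np.unique(fold_assignment)
        if len(fold_ids) < 2:
            raise ValueError("need at least 2 folds")
        splits = [
            (np.flatnonzero(fold_assignment != k), np.flatnonzero(fold_assignment == k))
            for k in fold_ids
        ]
    else:
        if folds < 2 or folds > n:
            raise ValueError(f"folds must be in [2, {n}]")
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        splits = list(kf.split(X))
    for tr, _ in splits:
        if len(tr) < 2:
            raise ValueError("a training fold has fewer than 2 rows")
    assignment = np.empty(n, dtype=int)
    for k, (_, va) in enumerate(splits):
        assignment[va] = k

    matrix = np.empty((n, len(learners)))
    for j, learner in enumerate(learners):
        for tr, va in splits:
            est = clone(learner.estimator)
            if isinstance(est, XGBRegressor):
                est.set_params(early_stopping_rounds=None)
            est.fit(X.iloc[tr], y[tr])
            matrix[va, j] = est.predict(X.iloc[va])
    return MetaFeatures(matrix=matrix, fold_assignment=assignment, labels=[l.label for l in learners])


def best_of_family(learners: list[TunedLearner]) -> list[TunedLearner]:
    best: dict[str, TunedLearner] = {}
    for t in learners:
        if t.family not in best or t.cv_rmse < best[t.family].cv_rmse:
            best[t.family] = t
    return [best[f] for f in FAMILIES if f in best]


def fit_stack(
    learners: list[TunedLearner],
    meta: MetaFeatures,
    y: np.ndarray,
    mode: str = "all_models",
    ridge_penalty: float = 1e-6,
    nonnegative: bool = False,
    feature_names: list[str] | None = None,
) -> StackModel:
    """Fit the GLM meta-learner on out-of-fold meta-features.

    ``all_models`` stacks every candidate; ``best_of_family`` keeps only the
    lowest-CV-RMSE candidate per family.  The meta-learner is ridge-regularized
    least squares (tiny default penalty — enough to absorb collinear
    meta-features without changing the fit materially); an optional
    non-negative variant constrains base weights to be >= 0.
    """
    y = np.asarray(y, dtype=float)
    if mode == "all_models":
        selected = list(learners)
    elif mode == "best_of_family":
        selected = best_of_family(learners)
    else:
        raise ValueError(f"unknown ensemble mode {mode!r}")
    if not selected:
        raise ValueError("no base learners to stack")
    cols = [meta.labels.index(t.label) for t in selected]
    M = meta.matrix[:, cols]

    if nonnegative:
        design = np.column_stack([np.ones(len(y)), M])
        lb = np.r_[-np.inf, np.zeros(M.shape[1])]
        sol = lsq_linear(design, y, bounds=(lb, np.inf))
        intercept, coefs = sol.x[0], sol.x[1:]
    else:
        ridge = Ridge(alpha=ridge_penalty)
        ridge.fit(M, y)
        intercept, coefs = float(ridge.intercept_), ridge.coef_
    return StackModel(
        learners=selected,
        intercept=float(intercept),
        coefs=np.asarray(coefs, dtype=float),
        mode=mode,
        feature_names=list(feature_names or []),
    )
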