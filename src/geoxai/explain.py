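"""Model-agnostic explainers: permutation importance, dependence profiles,
and break-down attributions.

Everything here treats the fitted model as a black box with a ``predict``
method over feature DataFrames.  Global explainers: permutation feature
importance (drop-out RMSE after permuting one feature), partial-dependence
(PD), local-dependence (LD) and accumulated-local (AL) profiles, and
two-variable PD surfaces.  Local explainer: break-down attributions, the
additive decomposition of one prediction into an intercept (mean model
prediction over the reference data) plus sequential per-feature
contributions; the default ordering is greedy (fix the feature that moves
the expected prediction the most at each step).

PD averages predictions with one feature clamped, so it extrapolates under
correlated features; LD conditions on a neighborhood of the grid point; AL
accumulates conditional finite differences and is the profile of choice when
features are correlated.  For an additive model AL and PD are parallel — the
diagnostic used to argue a fitted ensemble behaves additively in a feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import rmse as _rmse_loss

__all__ = [
    "FeatureImportance",
    "Profile",
    "Profile2D",
    "BreakDownAttribution",
    "permutation_importance",
    "pd_profile",
    "ld_profile",
    "al_profile",
    "pd_profile_2d",
    "break_down",
]


@dataclass
class FeatureImportance:
    """Per-feature drop-out losses. ``table`` is indexed by feature with
    columns permuted_loss, permuted_loss_sd, dropout_ratio, dropout_diff,
    ordered by mean permuted loss descending."""

    baseline_loss: float
    table: pd.DataFrame
    n_repeats: int
    seed: int

    def ranking(self) -> list[str]:
        return list(self.table.index)


@dataclass
class Profile:
    feature: str
    grid: np.ndarray
    yhat: np.ndarray
    kind: str  # PD | LD | AL
    interval_weights: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature, "kind": self.kind,
                             "grid": self.grid, "yhat": self.yhat})

    def slope(self) -> float:
        """Least-squares slope of the profile — exact for linear effects."""
        return float(np.polyfit(self.grid, self.yhat, 1)[0])


@dataclass
class Profile2D:
    feature_a: str
    feature_b: str
    grid_a: np.ndarray
    grid_b: np.ndarray
    yhat: np.ndarray  # len(grid_a) x len(grid_b)

    def cross_differences(self) -> np.ndarray:
        """Second-order finite differences: zero everywhere iff additive."""
        z = self.yhat
        return z[1:, 1:] - z[:-1, 1:] - z[1:, :-1] + z[:-1, :-1]


@dataclass
class BreakDownAttribution:
    """Additive decomposition: intercept + sum(deltas) = prediction."""

    unit_id: str | None
    intercept: float
    contributions: list[tuple[str, float, float]]  # (feature, value, delta)
    prediction: float
    ordering_rule: str  # greedy | fixed

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.contributions, columns=["feature", "value", "delta"]
        )

    def additivity_gap(self) -> float:
        total = self.intercept + sum(d for _, _, d in self.contributions)
        scale = max(abs(self.prediction), 1.0)
        return abs(total - self.prediction) / scale


def _predict(model, X) -> np.ndarray:
    return np.asarray(model.predict(X), dtype=float)


def permutation_importance(
    model,
    X: pd.DataFrame,
    y,
    loss=_rmse_loss,
    n_repeats: int = 10,
    seed: int = 0,
    features: list[str] | None = None,
) -> FeatureImportance:
    """Drop-out loss per feature: loss after permuting that column.

    Each repeat draws a fresh seeded permutation of the feature column and
    recomputes the loss on the same rows; the ratio permuted/baseline is the
    "factor by which the RMSE is increased" reading of importance, the
    difference the additive reading.  A perfect model (zero baseline loss)
    leaves ratios undefined; differences are still reported.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    y = np.asarray(y, dtype=float)
    features = list(X.columns) if features is None else list(features)
    baseline = float(loss(y, _predict(model, X)))
    if baseline == 0:
        warnings.warn("zero baseline loss: dropout ratios undefined", stacklevel=2)

    rng = np.random.default_rng(seed)
    rows = {}
    for f in features:
        losses = np.empty(n_repeats)
        for r in range(n_repeats):
            work = X.copy()
            work[f] = rng.permutation(work[f].to_numpy())
            losses[r] = loss(y, _predict(model, work))
        rows[f] = {
            "permuted_loss": losses.mean(),
            "permuted_loss_sd": losses.std(ddof=1) if n_repeats > 1 else 0.0,
            "dropout_ratio": losses.mean() / baseline if baseline > 0 else np.nan,
            "dropout_diff": losses.mean() - baseline,
        }
    table = pd.DataFrame.from_dict(rows, orient="index").sort_values(
        "permuted_loss", ascending=False
    )
    table.index.name = "feature"
    return FeatureImportance(baseline_loss=baseline, table=table,
                             n_repeats=n_repeats, seed=seed)


def _quantile_grid(x: np.ndarray, grid_size: int) -> np.ndarray:
    grid = np.unique(np.quantile(x, np.linspace(0, 1, grid_size)))
    if len(grid) < 2:
        raise ValueError("constant feature: no profile grid")
    return grid


def pd_profile(model, data: pd.DataFrame, feature: str, grid_size: int = 51) -> Profile:
    """Partial-dependence profile: mean prediction with the feature clamped.

    yhat(g) = mean_i model(x_i with feature := g) on a grid of empirical
    quantiles.
    """
    x = data[feature].to_numpy(dtype=float)
    grid = _quantile_grid(x, grid_size)
    yhat = np.empty(len(grid))
    work = data.copy()
    for k, g in enumerate(grid):
        work[feature] = g
        yhat[k] = _predict(model, work).mean()
    return Profile(feature, grid, yhat, "PD")


def ld_profile(
    model,
    data: pd.DataFrame,
    feature: str,
    grid_size: int = 51,
    neighborhood_frac: float = 0.25,
) -> Profile:
    """Local-dependence profile: conditional version of PD.

    At grid point g, predictions are averaged only over the rows whose
    feature value is among the nearest ``neighborhood_frac`` fraction of g
    (feature still clamped to g).  With fraction 1 this is exactly PD.
    """
    if not 0 < neighborhood_frac <= 1:
        raise ValueError("neighborhood_frac must be in (0, 1]")
    x = data[feature].to_numpy(dtype=float)
    grid = _quantile_grid(x, grid_size)
    m = max(1, int(np.ceil(neighborhood_frac * len(data))))
    yhat = np.empty(len(grid))
    for k, g in enumerate(grid):
        near = np.argsort(np.abs(x - g), kind="stable")[:m]
        work = data.iloc[near].copy()
        work[feature] = g
        yhat[k] = _predict(model, work).mean()
    return Profile(feature, grid, yhat, "LD")


def al_profile(model, data: pd.DataFrame, feature: str, n_intervals: int = 20) -> Profile:
    """Accumulated-local-effects profile.

    The feature range is cut at empirical quantiles into intervals; the local
    effect of interval k is the mean prediction difference when moving the
    rows that live in k from the interval's lower to its upper edge; the
    profile is the cumulative sum over intervals, mean-centered under the
    empirical interval weights (midpoint rule), so it is identified up to the
    level convention only.  Unlike PD it never evaluates the model far from
    the data, which is what makes it trustworthy under correlated features.
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    x = data[feature].to_numpy(dtype=float)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_intervals + 1)))
    if len(edges) < 3:
        raise ValueError("constant or near-constant feature: no AL intervals")
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(idx, minlength=len(edges) - 1)
    if (counts == 0).any():
        empty = int((counts == 0).sum())
        warnings.warn(f"merged {empty} empty AL interval(s) with neighbors", stacklevel=2)
        keep = np.r_[True, counts > 0]  # always keep the lower edge
        edges = edges[keep]
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
        counts = np.bincount(idx, minlength=len(edges) - 1)

    effects = np.zeros(len(edges) - 1)
    for k in range(len(edges) - 1):
        rows = np.flatnonzero(idx == k)
        if len(rows) == 0:
            continue
        work = data.iloc[rows].copy()
        work[feature] = edges[k + 1]
        hi = _predict(model, work)
        work[feature] = edges[k]
        lo = _predict(model, work)
        effects[k] = (hi - lo).mean()

    cum = np.r_[0.0, np.cumsum(effects)]
    wts = counts / counts.sum()
    center = float((wts * (cum[:-1] + cum[1:]) / 2.0).sum())
    return Profile(feature, edges, cum - center, "AL", interval_weights=wts)


def pd_profile_2d(
    model,
    data: pd.DataFrame,
    feature_a: str,
    feature_b: str,
    grid_sizes: tuple[int, int] = (21, 21),
) -> Profile2D:
    """Two-variable partial dependence: the joint-effect surface."""
    grid_a = _quantile_grid(data[feature_a].to_numpy(dtype=float), grid_sizes[0])
    grid_b = _quantile_grid(data[feature_b].to_numpy(dtype=float), grid_sizes[1])
    yhat = np.empty((len(grid_a), len(grid_b)))
    work = data.copy()
    for i, ga in enumerate(grid_a):
        work[feature_a] = ga
        for j, gb in enumerate(grid_b):
            work[feature_b] = gb
            yhat[i, j] = _predict(model, work).mean()
    return Profile2D(feature_a, feature_b, grid_a, grid_b, yhat)


def _expected_with_fixed(model, data: pd.DataFrame, fixed: dict[str, float]) -> float:
    work = data.copy()
    for f, v in fixed.items():
        work[f] = v
    return float(_predict(model, work).mean())


def break_down(
    model,
    data: pd.DataFrame,
    observation,
    order: list[str] | None = None,
    features: list[str] | None = None,
    unit_id: str | None = None,
    n_ref: int | None = None,
    seed: int = 0,
) -> BreakDownAttribution:
    """Break-down attribution of one prediction.

    The intercept is the mean model prediction over the reference data.
    Features are then fixed one at a time at the observation's values; the
    contribution of feature j is the change in the expected prediction when
    it joins the already-fixed set.  With an explicit ``order`` the sequence
    is as given; otherwise the order is greedy — at each step fix the feature
    with the largest absolute change, ties broken lexicographically.  Because
    the deltas telescope, intercept + sum(deltas) equals the model's
    prediction for the observation exactly.

    ``n_ref`` subsamples the reference data (seeded) for speed on large maps.
    """
    if isinstance(observation, pd.DataFrame):
        if len(observation) != 1:
            raise ValueError("observation must be a single row")
        observation = observation.iloc[0]
    features = list(data.columns) if features is None else list(features)
    missing = [f for f in features if f not in observation.index]
    if missing:
        raise ValueError(f"observation lacks features: {missing}")
    if order is not None:
        bad = [f for f in order if f not in features]
        if bad:
            raise ValueError(f"ordered features not in model features: {bad}")
        if sorted(order) != sorted(features):
            raise ValueError("order must cover exactly the model features")

    ref = data
    if n_ref is not None and n_ref < len(data):
        rng = np.random.default_rng(seed)
        ref = data.iloc[rng.choice(len(data), size=n_ref, replace=False)]

    intercept = float(_predict(model, ref).mean())
    fixed: dict[str, float] = {}
    contributions: list[tuple[str, float, float]] = []
    e_prev = intercept

    if order is not None:
        for f in order:
            fixed[f] = observation[f]
            e_new = _expected_with_fixed(model, ref, fixed)
            contributions.append((f, observation[f], e_new - e_prev))
            e_prev = e_new
        rule = "fixed"
    else:
        remaining = sorted(features)
        while remaining:
            candidates = []
            for f in remaining:
                e_f = _expected_with_fixed(model, ref, {**fixed, f: observation[f]})
                candidates.append((-abs(e_f - e_prev), f, e_f))
            candidates.sort()  # most-influential first, lexicographic on ties
            _, f, e_new = candidates[0]
            fixed[f] = observation[f]
            contributions.append((f, observation[f], e_new - e_prev))
            e_prev = e_new
            remaining.remove(f)
        rule = "greedy"

    # With every model feature fixed, the reference rows all coincide with the
    # observation, so e_prev IS the model's prediction for it; with a feature
    # subset it is the conditional expectation given the fixed subset.
    prediction = e_prev
    return BreakDownAttribution(
        unit_id=unit_id,
        intercept=intercept,
        contributions=contributions,
        prediction=prediction,
        ordering_rule=rule,
    )
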