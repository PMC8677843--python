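"""Model performance metrics and resampling bias-variance decomposition.

MAE and RMSE are the headline prediction-error metrics; goodness of fit is
the squared Pearson correlation of the observed-vs-predicted regression.
The bias-variance decomposition refits a model on bootstrap resamples of the
training pool and evaluates on a fixed test set:

    Err(x) = Bias^2(x) + Var(x) + sigma^2

with Bias(x) = E[fhat(x)] - f(x) and Var(x) = E[fhat(x)^2] - E[fhat(x)]^2.
On synthetic data the true surface f(x) is known (``truth_fn``); on observed
data bias is measured against the observed responses and labeled as such.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EvalReport",
    "BiasVarianceReport",
    "mae",
    "rmse",
    "goodness_of_fit",
    "evaluate",
    "bias_variance",
]


@dataclass
class EvalReport:
    mae: float
    rmse: float
    r2: float
    n: int

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "r2": self.r2, "n": self.n}


@dataclass
class BiasVarianceReport:
    """Aggregate decomposition over the test points.

    ``bias_sq`` is measured against the true surface when ``truth_known``,
    otherwise against the observed responses. ``total_err`` is the mean (over
    resamples and test points) squared error against the observed responses,
    so on synthetic data total_err ~ bias_sq + variance + sigma^2.
    """

    bias_sq: float
    variance: float
    total_err: float
    irreducible_sigma_sq: float | None
    n_resamples: int
    truth_known: bool

    @property
    def closure_gap(self) -> float | None:
        """Relative gap |total - (bias^2 + var + sigma^2)| / total, if truth known."""
        if not self.truth_known or self.irreducible_sigma_sq is None:
            return None
        expected = self.bias_sq + self.variance + self.irreducible_sigma_sq
        return abs(self.total_err - expected) / self.total_err


def _check_pair(observed, predicted):
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have the same length")
    if y.size == 0:
        raise ValueError("empty vectors")
    return y, yhat


def mae(observed, predicted) -> float:
    """Mean absolute error (1/n) * sum |y_i - yhat_i|."""
    y, yhat = _check_pair(observed, predicted)
    return float(np.mean(np.abs(y - yhat)))


def rmse(observed, predicted) -> float:
    """Root mean squared error sqrt((1/n) * sum (y_i - yhat_i)^2)."""
    y, yhat = _check_pair(observed, predicted)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def goodness_of_fit(observed, predicted) -> float:
    """R^2 of the simple linear regression of observed on predicted.

    Equals the squared Pearson correlation, so it is invariant to affine
    recalibration of the predictions.  Undefined for constant predictions.
    """
    y, yhat = _check_pair(observed, predicted)
    if y.size < 3:
        raise ValueError("goodness of fit needs n >= 3")
    if np.std(yhat) == 0:
        raise ValueError("R^2 undefined for constant predictions")
    if np.std(y) == 0:
        raise ValueError("R^2 undefined for constant observations")
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r**2)


def evaluate(observed, predicted) -> EvalReport:
    y, yhat = _check_pair(observed, predicted)
    return EvalReport(
        mae=mae(y, yhat), rmse=rmse(y, yhat), r2=goodness_of_fit(y, yhat), n=len(y)
    )


def bias_variance(
    model_factory,
    pool_X: pd.DataFrame,
    pool_y,
    test_X: pd.DataFrame,
    test_y,
    truth_fn=None,
    noise_sd: float | None = None,
    n_resamples: int = 10,
    resample_size: int | None = None,
    seed: int = 0,
) -> BiasVarianceReport:
    """Bootstrap bias-variance decomposition of a model-building recipe.

    ``model_factory()`` must return a fresh unfitted model exposing
    fit(X, y) / predict(X).  The training pool is resampled with replacement
    (``resample_size`` rows, the full pool size by default) ``n_resamples``
    times — ten by default, matching the study protocol of rerunning each
    model with ten resampled training sets — the model is refit each time,
    and predictions are collected on the fixed test set.  ``truth_fn(test_X)``
    supplies the noiseless surface when known.

    The squared-bias estimate subtracts the Monte-Carlo inflation
    variance/n_resamples (the naive plug-in estimator of a squared mean is
    biased upward by exactly that amount), floored at zero.
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    pool_y = np.asarray(pool_y, dtype=float)
    test_y = np.asarray(test_y, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(pool_y)
    m = n if resample_size is None else int(resample_size)

    preds = np.empty((n_resamples, len(test_y)))
    sq_err = np.empty(n_resamples)
    for r in range(n_resamples):
        idx = rng.integers(0, n, size=m)
        by = pool_y[idx]
        if np.std(by) == 0:
            raise ValueError("degenerate resample: constant response")
        model = model_factory()
        model.fit(pool_X.iloc[idx], by)
        preds[r] = model.predict(test_X)
        sq_err[r] = np.mean((preds[r] - test_y) ** 2)

    mean_pred = preds.mean(axis=0)
    variance = float(np.mean(preds.var(axis=0)))
    truth_known = truth_fn is not None
    target = np.asarray(truth_fn(test_X), dtype=float) if truth_known else test_y
    bias_sq = float(
        max(np.mean((mean_pred - target) ** 2) - variance / n_resamples, 0.0)
    )
    return BiasVarianceReport(
        bias_sq=bias_sq,
        variance=variance,
        total_err=float(sq_err.mean()),
        irreducible_sigma_sq=(noise_sd**2 if noise_sd is not None else None),
        n_resamples=n_resamples,
        truth_known=truth_known,
    )
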