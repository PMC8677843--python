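import warnings

import numpy as np
import pytest

from geoxai import (
    LatticeSpec,
    contiguity_weights,
    fit_gw_ols,
    fit_spatial_error,
    fit_spatial_lag,
    make_lattice,
    select_bandwidth,
)


def _lattice_weights(n_side):
    table = make_lattice(LatticeSpec(n_side, n_side))
    w = contiguity_weights(table, "rook").row_standardized()
    return table, w


def _simulate_lag(n_side, rho, beta=(1.0, 2.0, -1.0), noise=1.0, seed=0):
    table, w = _lattice_weights(n_side)
    n = n_side**2
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    Wd = w.sparse().toarray()
    xb = beta[0] + X @ np.asarray(beta[1:])
    eps = rng.normal(0, noise, n)
    y = np.linalg.solve(np.eye(n) - rho * Wd, xb + eps)
    return y, X, w, table


class TestSpatialLag:
    def test_zero_rho_recovers_ols(self):
        # zero true intercept: otherwise the intercept absorbs rho_hat * ybar
        # and the comparison conflates sampling error of rho with the betas
        y, X, w, _ = _simulate_lag(30, rho=0.0, beta=(0.0, 2.0, -1.0), seed=1)
        fit = fit_spatial_lag(y, X, w)
        assert abs(fit.rho_or_lambda) < 0.05
        ols_beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )
        np.testing.assert_allclose(fit.betas, ols_beta, atol=1e-2)

    def test_recovers_moderate_rho(self):
        y, X, w, _ = _simulate_lag(30, rho=0.5, seed=2)
        fit = fit_spatial_lag(y, X, w)
        assert 0.4 <= fit.rho_or_lambda <= 0.6

    def test_profile_optimality_vs_rho_zero(self):
        y, X, w, _ = _simulate_lag(20, rho=0.3, seed=3)
        fit = fit_spatial_lag(y, X, w)
        n = len(y)
        Xd = np.column_stack([np.ones(n), X])
        beta0, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        e0 = y - Xd @ beta0
        s0 = e0 @ e0 / n
        ll0 = -0.5 * n * (np.log(2 * np.pi * s0) + 1.0)  # log-det term is 0 at rho=0
        assert fit.loglik >= ll0 - 1e-8

    def test_requires_row_standardized(self):
        table = make_lattice(LatticeSpec(5, 5))
        w = contiguity_weights(table, "rook")  # binary, not row-standardized
        with pytest.raises(ValueError, match="row-standardized"):
            fit_spatial_lag(np.arange(25.0), np.ones((25, 1)), w)

    def test_singular_design_rejected(self):
        y, X, w, _ = _simulate_lag(10, rho=0.0, seed=4)
        X2 = np.column_stack([X, X[:, 0]])  # duplicate column
        with pytest.raises(ValueError, match="singular"):
            fit_spatial_lag(y, X2, w)


class TestSpatialError:
    def test_recovers_moderate_lambda(self):
        table, w = _lattice_weights(30)
        n = 900
        rng = np.random.default_rng(5)
        X = rng.normal(size=(n, 2))
        Wd = w.sparse().toarray()
        u = np.linalg.solve(np.eye(n) - 0.5 * Wd, rng.normal(0, 1, n))
        y = 1.0 + X @ np.array([2.0, -1.0]) + u
        fit = fit_spatial_error(y, X, w)
        assert 0.35 <= fit.rho_or_lambda <= 0.65
        np.testing.assert_allclose(fit.betas[1:], [2.0, -1.0], atol=0.1)

    def test_zero_lambda_matches_ols(self):
        table, w = _lattice_weights(20)
        rng = np.random.default_rng(6)
        X = rng.normal(size=(400, 2))
        y = 0.5 + X @ np.array([1.0, 1.0]) + rng.normal(0, 1, 400)
        fit = fit_spatial_error(y, X, w)
        assert abs(fit.rho_or_lambda) < 0.12
        ols_beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(400), X]), y, rcond=None
        )
        np.testing.assert_allclose(fit.betas, ols_beta, atol=0.05)


class TestGWOLS:
    def _data(self, n_side=20, seed=7):
        table = make_lattice(LatticeSpec(n_side, n_side))
        rng = np.random.default_rng(seed)
        n = n_side**2
        X = rng.normal(size=(n, 2))
        coords = table[["x", "y"]].to_numpy()
        return table, X, coords, rng

    def test_huge_bandwidth_equals_global_ols(self):
        table, X, coords, rng = self._data()
        y = 1.0 + X @ np.array([2.0, -1.0]) + rng.normal(0, 1, len(X))
        extent = np.linalg.norm(coords.max(axis=0) - coords.min(axis=0))
        fit = fit_gw_ols(y, X, coords, bandwidth=1e4 * extent)
        ols_beta, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), X]), y, rcond=None
        )
        assert np.max(np.abs(fit.local_betas.to_numpy() - ols_beta)) < 1e-6

    def test_scale_equivariance(self):
        table, X, coords, rng = self._data(seed=8)
        y = 1.0 + X @ np.array([1.0, 0.5]) + rng.normal(0, 0.5, len(X))
        a = fit_gw_ols(y, X, coords, bandwidth=3.0)
        b = fit_gw_ols(y, X, coords * 2.0, bandwidth=6.0)
        np.testing.assert_allclose(
            a.local_betas.to_numpy(), b.local_betas.to_numpy(), atol=1e-10
        )

    def test_recovers_spatially_varying_slope(self):
        table, X, coords, rng = self._data(n_side=40, seed=9)
        slope = 1.0 + coords[:, 0] / coords[:, 0].max()  # west-east gradient
        y = slope * X[:, 0] + rng.normal(0, 0.3, len(X))
        fit = fit_gw_ols(y, X[:, :1], coords, bandwidth=4.0)
        r = np.corrcoef(fit.local_betas["x0"], slope)[0, 1]
        assert r > 0.7

    def test_tiny_bandwidth_rejected(self):
        table, X, coords, rng = self._data()
        y = rng.normal(size=len(X))
        with pytest.raises(ValueError, match="effective sample"):
            fit_gw_ols(y, X, coords, bandwidth=0.05)

    def test_bandwidth_selection_runs(self):
        table, X, coords, rng = self._data(n_side=10, seed=10)
        y = 1.0 + X @ np.array([1.0, -1.0]) + rng.normal(0, 0.5, len(X))
        best, cv = select_bandwidth(y, X, coords, n_candidates=6)
        assert best > 0
        assert np.isfinite(cv["cv_rmse"]).any()
        assert best == cv.loc[cv["cv_rmse"].idxmin(), "bandwidth"]

    def test_predict_at_new_locations(self):
        table, X, coords, rng = self._data(seed=11)
        y = 2.0 + X @ np.array([1.0, 1.0]) + rng.normal(0, 0.2, len(X))
        fit = fit_gw_ols(y[:300], X[:300], coords[:300], bandwidth=5.0)
        preds = fit.predict(X[300:], coords[300:])
        assert np.corrcoef(preds, y[300:])[0, 1] > 0.9


class TestModelOrdering:
    def test_stack_beats_gwols_beats_lag_on_nonlinear_surface(self):
        """On a strongly nonlinear surface with an interaction, test RMSE
        orders stack < GW-OLS < spatial lag in at least 7 of 10 seeds."""
        from geoxai import (
            distance_band_weights,
            fit_stack,
            gi_star,
            nonlinear_effect_spec,
            oof_predictions,
            simulate_response,
            simulate_risk_factors,
            stratified_split,
            tune_learners,
        )
        from geoxai.evaluation import rmse
        from geoxai.learners import feature_columns, small_grids

        wins = 0
        for s in range(300, 310):
            t = make_lattice(LatticeSpec(40, 40))
            t = simulate_risk_factors(t, seed=s)
            t = simulate_response(t, nonlinear_effect_spec(), seed=s + 1)
            w = contiguity_weights(t, "queen", include_self=True)
            t["gi_bin"] = gi_star(t["response"], w).gi_bin
            a = stratified_split(t, "gi_bin", seed=s + 2)
            factors = feature_columns(t)
            tr, te = a.mask("train"), a.mask("test")
            X, y = t[factors], t["response"].to_numpy()
            learners = tune_learners(small_grids(), X[tr], y[tr], folds=3, seed=s + 3)
            meta = oof_predictions(learners, X[tr], y[tr], folds=3, seed=s + 3)
            stack = fit_stack(learners, meta, y[tr])
            r_stack = rmse(y[te], stack.predict(X[te]))

            Xtr, Xte = X[tr].to_numpy(float), X[te].to_numpy(float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                w_tr = distance_band_weights(t[tr], 1.5).row_standardized()
            lag = fit_spatial_lag(y[tr], Xtr, w_tr)
            r_lag = rmse(y[te], lag.trend(Xte))

            ctr = t.loc[tr, ["x", "y"]].to_numpy()
            cte = t.loc[te, ["x", "y"]].to_numpy()
            extent = np.linalg.norm(ctr.max(0) - ctr.min(0))
            bw = extent / 6
            while True:
                try:
                    gw = fit_gw_ols(y[tr], Xtr, ctr, bw)
                    break
                except ValueError:
                    bw *= 1.5
            r_gw = rmse(y[te], gw.predict(Xte, cte))
            wins += r_stack < r_gw < r_lag
        assert wins >= 7
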