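import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import Ridge

from geoxai import (
    al_profile,
    break_down,
    ld_profile,
    pd_profile,
    pd_profile_2d,
    permutation_importance,
)
from conftest import LinearPredictor
from oracles import breakdown_fixed_brute, greedy_order_brute


class SurfaceModel:
    """Adapter: the generator's noiseless truth surface as a predictor."""

    def __init__(self, eff):
        self.eff = eff

    def predict(self, X):
        return self.eff.surface(X)


def _correlated_pair(n=2000, rho=0.8, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rho * a + np.sqrt(1 - rho**2) * rng.normal(size=n)
    return pd.DataFrame({"a": a, "b": b})


class TestPermutationImportance:
    def test_noise_feature_ratio_near_one(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(
            {"signal": rng.normal(size=2000), "noise": rng.normal(size=2000)}
        )
        y = 3.0 * X["signal"].to_numpy() + rng.normal(0, 1, 2000)
        model = Ridge(alpha=1.0).fit(X, y)
        imp = permutation_importance(model, X, y, n_repeats=20, seed=0)
        assert 0.9 <= imp.table.loc["noise", "dropout_ratio"] <= 1.1
        assert imp.table.loc["signal", "dropout_ratio"] > 1.5
        assert imp.ranking()[0] == "signal"

    def test_sole_informative_feature_ratio_above_one(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame({"a": rng.normal(size=500)})
        y = 2.0 * X["a"].to_numpy() + rng.normal(0, 0.3, 500)
        imp = permutation_importance(LinearPredictor(0.0, {"a": 2.0}), X, y, seed=1)
        assert imp.table.loc["a", "dropout_ratio"] > 1.0

    def test_seeded_determinism(self, linear_frame, linear_model):
        X, y, _ = linear_frame
        a = permutation_importance(linear_model, X, y, n_repeats=5, seed=7)
        b = permutation_importance(linear_model, X, y, n_repeats=5, seed=7)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.baseline_loss == b.baseline_loss

    def test_zero_baseline_warns(self, linear_frame, linear_model):
        X, _, _ = linear_frame
        y = linear_model.predict(X)  # exactly reproducible -> zero loss
        with pytest.warns(UserWarning, match="zero baseline"):
            imp = permutation_importance(linear_model, X, y, n_repeats=2, seed=0)
        assert np.isnan(imp.table["dropout_ratio"]).all()
        assert (imp.table["dropout_diff"] >= 0).all()


class TestPDProfile:
    def test_linear_slope_exact(self, linear_frame, linear_model):
        X, _, beta = linear_frame
        prof = pd_profile(linear_model, X, "a")
        slopes = np.diff(prof.yhat) / np.diff(prof.grid)
        np.testing.assert_allclose(slopes, beta["a"], rtol=1e-10)

    def test_constant_model_flat(self, linear_frame):
        X, _, _ = linear_frame
        prof = pd_profile(LinearPredictor(4.0, {}), X, "a")
        np.testing.assert_allclose(prof.yhat, 4.0)

    def test_recovers_generator_truth(self, counties_small):
        """PD of the true surface equals the analytic PD of the generator."""
        eff = counties_small.attrs["effect_spec"]
        model = SurfaceModel(eff)
        X = counties_small[eff.features()]
        prof = pd_profile(model, X, "elevation", grid_size=21)
        truth = eff.partial_dependence("elevation", prof.grid, X)
        rng_ = truth.max() - truth.min()
        assert np.max(np.abs(prof.yhat - truth)) < 0.02 * rng_

    def test_constant_feature_rejected(self):
        X = pd.DataFrame({"a": np.ones(10)})
        with pytest.raises(ValueError, match="constant"):
            pd_profile(LinearPredictor(0.0, {"a": 1.0}), X, "a")


class TestLDProfile:
    def test_frac_one_equals_pd(self, linear_frame, linear_model):
        X, _, _ = linear_frame
        ld = ld_profile(linear_model, X, "a", neighborhood_frac=1.0)
        pdp = pd_profile(linear_model, X, "a")
        np.testing.assert_allclose(ld.yhat, pdp.yhat)

    def test_independent_features_ld_close_to_pd(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=4000), "b": rng.normal(size=4000)})
        y = 2.0 * X["a"] + 1.0 * X["b"] + rng.normal(0, 0.5, 4000)
        model = Ridge(alpha=1.0).fit(X, y)
        ld = ld_profile(model, X, "a", grid_size=21, neighborhood_frac=0.2)
        pdp = pd_profile(model, X, "a", grid_size=21)
        rng_ = pdp.yhat.max() - pdp.yhat.min()
        assert np.max(np.abs(ld.yhat - pdp.yhat)) < 0.05 * rng_

    def test_constant_model_flat(self, linear_frame):
        X, _, _ = linear_frame
        prof = ld_profile(LinearPredictor(1.0, {}), X, "a", neighborhood_frac=0.3)
        np.testing.assert_allclose(prof.yhat, 1.0)


class TestALProfile:
    def test_linear_slope_under_correlation(self):
        X = _correlated_pair()
        model = LinearPredictor(0.0, {"a": 2.0, "b": 1.0})
        prof = al_profile(model, X, "a", n_intervals=20)
        assert prof.slope() == pytest.approx(2.0, rel=0.02)

    def test_ignored_feature_identically_zero(self):
        X = _correlated_pair()
        prof = al_profile(LinearPredictor(3.0, {"b": 1.0}), X, "a")
        np.testing.assert_allclose(prof.yhat, 0.0, atol=1e-12)

    def test_mean_centering_invariant(self):
        X = _correlated_pair(seed=2)
        model = LinearPredictor(1.0, {"a": -1.5, "b": 0.5})
        prof = al_profile(model, X, "a", n_intervals=15)
        mid = (prof.yhat[:-1] + prof.yhat[1:]) / 2
        assert abs((prof.interval_weights * mid).sum()) < 1e-10

    def test_parallel_to_pd_for_additive_fit(self):
        """For an additive fitted model AL and PD differ by a constant."""
        rng = np.random.default_rng(6)
        X = _correlated_pair(n=2000, rho=0.7, seed=6)
        y = 2.0 * X["a"] + 1.0 * X["b"] + rng.normal(0, 0.5, 2000)
        model = Ridge(alpha=1.0).fit(X, y)
        al = al_profile(model, X, "a", n_intervals=20)
        pdp = pd_profile(model, X, "a", grid_size=40)
        pd_at_edges = np.interp(al.grid, pdp.grid, pdp.yhat)
        gap = al.yhat - pd_at_edges
        rng_ = pdp.yhat.max() - pdp.yhat.min()
        assert np.std(gap) < 0.02 * rng_


class TestPD2D:
    def test_additive_model_zero_cross_differences(self, linear_frame, linear_model):
        X, _, _ = linear_frame
        prof = pd_profile_2d(linear_model, X, "a", "b", grid_sizes=(9, 9))
        np.testing.assert_allclose(prof.cross_differences(), 0.0, atol=1e-10)

    def test_threshold_interaction_localised(self, counties_small):
        """Cross-differences of the truth surface appear only above the
        smoking threshold where the poverty interaction switches on."""
        eff = counties_small.attrs["effect_spec"]
        model = SurfaceModel(eff)
        X = counties_small[eff.features()]
        prof = pd_profile_2d(model, X, "smoking", "poverty", grid_sizes=(15, 9))
        cd = np.abs(prof.cross_differences()).sum(axis=1)
        below = prof.grid_a[1:] <= 30.0
        assert cd[below].sum() < 1e-9
        assert cd[~below].sum() > 0.1

    def test_argument_symmetry(self, counties_small):
        eff = counties_small.attrs["effect_spec"]
        model = SurfaceModel(eff)
        X = counties_small[eff.features()]
        ab = pd_profile_2d(model, X, "smoking", "poverty", grid_sizes=(7, 7))
        ba = pd_profile_2d(model, X, "poverty", "smoking", grid_sizes=(7, 7))
        np.testing.assert_allclose(ab.yhat, ba.yhat.T, atol=1e-10)


class TestBreakDown:
    def test_linear_deltas_order_invariant(self, linear_frame, linear_model):
        X, _, beta = linear_frame
        obs = X.iloc[17]
        means = X.mean()
        for order in (["a", "b", "c"], ["c", "b", "a"], ["b", "a", "c"]):
            bd = break_down(linear_model, X, obs, order=order)
            for f, _, delta in bd.contributions:
                assert delta == pytest.approx(beta[f] * (obs[f] - means[f]), abs=1e-9)
        greedy = break_down(linear_model, X, obs)
        for f, _, delta in greedy.contributions:
            assert delta == pytest.approx(beta[f] * (obs[f] - means[f]), abs=1e-9)

    def test_additivity(self, linear_frame, linear_model):
        X, _, _ = linear_frame
        for i in (0, 5, 100):
            bd = break_down(linear_model, X, X.iloc[i])
            assert bd.additivity_gap() < 1e-9
            assert bd.prediction == pytest.approx(
                linear_model.predict(X.iloc[[i]])[0], rel=1e-9
            )

    def test_matches_fixed_order_brute_force(self, linear_frame):
        X, _, _ = linear_frame
        model = LinearPredictor(2.0, {"a": 1.0, "b": -2.0, "c": 0.5})
        obs = X.iloc[3]
        order = ["b", "c", "a"]
        bd = break_down(model, X, obs, order=order)
        intercept, deltas = breakdown_fixed_brute(model.predict, X, obs, order)
        assert bd.intercept == pytest.approx(intercept)
        np.testing.assert_allclose([d for _, _, d in bd.contributions], deltas)

    def test_greedy_matches_exhaustive_on_toy(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=["p", "q", "r"])

        class Interacting:
            def predict(self, Z):
                z = Z.to_numpy(dtype=float)
                return 3.0 * z[:, 0] * z[:, 1] + 1.5 * z[:, 2] + 0.5 * z[:, 1]

        model = Interacting()
        for i in (0, 11, 25):
            obs = X.iloc[i]
            bd = break_down(model, X, obs)
            expected = greedy_order_brute(model.predict, X, obs, ["p", "q", "r"])
            assert [f for f, _, _ in bd.contributions] == expected

    def test_unknown_feature_in_order_rejected(self, linear_frame, linear_model):
        X, _, _ = linear_frame
        with pytest.raises(ValueError, match="ghost"):
            break_down(linear_model, X, X.iloc[0], order=["a", "b", "ghost"])

    def test_reference_subsample_deterministic(self, linear_frame, linear_model):
        X, _, _ = linear_frame
        a = break_down(linear_model, X, X.iloc[9], n_ref=100, seed=5)
        b = break_down(linear_model, X, X.iloc[9], n_ref=100, seed=5)
        assert a.intercept == b.intercept
        assert a.contributions == b.contributions
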