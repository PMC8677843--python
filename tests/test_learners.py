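import inspect

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator, RegressorMixin

from geoxai import LearnerSpec, fit_stack, oof_predictions, random_grid_search, tune_learners
from geoxai.learners import DEFAULT_EARLY_STOP, TunedLearner, best_of_family


class TruthEstimator(BaseEstimator, RegressorMixin):
    """Oracle learner: ignores training and returns the known linear truth."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return 5.0 + 2.0 * np.asarray(X["a"], dtype=float)


class MemorizeMean(BaseEstimator, RegressorMixin):
    """Predicts the mean of its training responses — leakage probe."""

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        return np.full(len(X), self.mean_)


def _linear_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
    y = 5.0 + 2.0 * X["a"].to_numpy() + rng.normal(0, 0.1, n)
    return X, y


class TestRandomGridSearch:
    def test_single_combination_returned(self):
        X, y = _linear_data()
        spec = LearnerSpec("penalized-linear", {"penalty": [1.0], "l1_ratio": [0.0]})
        out = random_grid_search(spec, X, y, folds=3, seed=0)
        assert len(out) == 1
        assert out[0].params == {"l1_ratio": 0.0, "penalty": 1.0}
        assert out[0].cv_rmse > 0

    def test_budget_caps_combinations(self):
        X, y = _linear_data()
        spec = LearnerSpec(
            "penalized-linear",
            {"penalty": [0.01, 0.1, 1.0, 10.0], "l1_ratio": [0.0, 0.5]},
            budget=3,
        )
        out = random_grid_search(spec, X, y, folds=3, seed=0)
        assert len(out) == 3

    def test_candidates_sorted_by_cv_rmse(self):
        X, y = _linear_data()
        spec = LearnerSpec("penalized-linear", {"penalty": [0.01, 100.0], "l1_ratio": [0.0]})
        out = random_grid_search(spec, X, y, folds=3, seed=0)
        assert out[0].cv_rmse <= out[1].cv_rmse

    def test_early_stop_recorded_in_card(self):
        X, y = _linear_data()
        spec = LearnerSpec(
            "gradient-boosting", {"n_estimators": [50], "max_depth": [2]}
        )
        out = random_grid_search(spec, X, y, folds=3, seed=0)
        card = out[0].card()
        assert card["early_stop"]["stopping_tolerance"] == 0.001
        assert card["early_stop"]["stopping_rounds"] == 2
        assert spec.early_stop == DEFAULT_EARLY_STOP

    def test_tenfold_is_default(self):
        sig = inspect.signature(random_grid_search)
        assert sig.parameters["folds"].default == 10

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            LearnerSpec("support-vector", {"C": [1.0]})


def _oracle_learner():
    return TunedLearner(
        family="penalized-linear",
        params={},
        cv_rmse=0.0,
        estimator=TruthEstimator(),
        label="oracle#0",
    )


class TestOOFPredictions:
    def test_perfect_learner_reproduces_truth(self):
        X, _ = _linear_data()
        truth = 5.0 + 2.0 * X["a"].to_numpy()
        meta = oof_predictions([_oracle_learner()], X, truth, folds=4, seed=0)
        np.testing.assert_allclose(meta.column("oracle#0"), truth)

    def test_leave_one_out_no_leakage(self):
        X, _ = _linear_data(n=20)
        y = np.arange(20.0)
        lrn = TunedLearner("penalized-linear", {}, 0.0, MemorizeMean(), label="m#0")
        meta = oof_predictions([lrn], X, y, folds=20, seed=0)
        # OOF value for row i is the mean of everyone else's y
        for i in range(20):
            expected = (y.sum() - y[i]) / 19.0
            assert meta.matrix[i, 0] == pytest.approx(expected)

    def test_permutation_equivariance(self):
        X, y = _linear_data(n=60)
        lrn = TunedLearner("penalized-linear", {}, 0.0, MemorizeMean(), label="m#0")
        base = oof_predictions([lrn], X, y, folds=5, seed=1)
        rng = np.random.default_rng(2)
        perm = rng.permutation(60)
        shuffled = oof_predictions(
            [lrn],
            X.iloc[perm].reset_index(drop=True),
            y[perm],
            fold_assignment=base.fold_assignment[perm],
        )
        inv = np.empty_like(perm)
        inv[perm] = np.arange(60)
        np.testing.assert_allclose(shuffled.matrix[inv, 0], base.matrix[:, 0])

    def test_corruption_localised_to_other_folds(self):
        """Corrupting row i must not move OOF predictions inside i's own fold."""
        X, y = _linear_data(n=50)
        lrn = TunedLearner("penalized-linear", {}, 0.0, MemorizeMean(), label="m#0")
        clean = oof_predictions([lrn], X, y, folds=5, seed=3)
        y2 = y.copy()
        y2[7] += 1000.0
        dirty = oof_predictions([lrn], X, y2, folds=5, seed=3)
        fold_of_7 = clean.fold_assignment[7]
        same_fold = clean.fold_assignment == fold_of_7
        np.testing.assert_allclose(dirty.matrix[same_fold, 0], clean.matrix[same_fold, 0])
        assert not np.allclose(dirty.matrix[~same_fold, 0], clean.matrix[~same_fold, 0])


class TestStack:
    def test_oracle_base_gets_unit_weight(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        y = 5.0 + 2.0 * X["a"].to_numpy() + rng.normal(0, 0.5, 1000)
        lrn = _oracle_learner()
        meta = oof_predictions([lrn], X, y, folds=5, seed=0)
        stack = fit_stack([lrn], meta, y)
        assert stack.coefs[0] == pytest.approx(1.0, abs=0.05)
        assert abs(stack.intercept) <= 0.05 * np.std(y)

    def test_prediction_is_affine_in_bases(self):
        X, y = _linear_data(n=150)
        specs = [
            LearnerSpec("penalized-linear", {"penalty": [0.1, 1.0], "l1_ratio": [0.0]}),
            LearnerSpec("random-forest", {"n_estimators": [20], "max_depth": [4]}),
        ]
        learners = tune_learners(specs, X, y, folds=3, seed=0)
        meta = oof_predictions(learners, X, y, folds=3, seed=0)
        stack = fit_stack(learners, meta, y, mode="all_models")
        manual = stack.intercept + stack.base_predictions(X) @ stack.coefs
        np.testing.assert_allclose(stack.predict(X), manual)

    def test_best_of_family_selects_one_per_family(self):
        X, y = _linear_data(n=150)
        specs = [
            LearnerSpec("penalized-linear", {"penalty": [0.1, 1.0], "l1_ratio": [0.0]}),
            LearnerSpec("random-forest", {"n_estimators": [20, 30], "max_depth": [4]}),
        ]
        learners = tune_learners(specs, X, y, folds=3, seed=0)
        assert len(learners) == 4
        stack = fit_stack(learners, oof_predictions(learners, X, y, folds=3, seed=0),
                          y, mode="best_of_family")
        fams = [t.family for t in stack.learners]
        assert sorted(fams) == ["penalized-linear", "random-forest"]
        for t in stack.learners:
            rivals = [r for r in learners if r.family == t.family]
            assert t.cv_rmse == min(r.cv_rmse for r in rivals)

    def test_collinear_meta_features_survive(self):
        """Duplicate base learners must not crash the ridge meta-fit."""
        X, y = _linear_data(n=100)
        l1 = _oracle_learner()
        l2 = TunedLearner("penalized-linear", {}, 0.0, TruthEstimator(), label="oracle#1")
        meta = oof_predictions([l1, l2], X, y, folds=4, seed=0)
        stack = fit_stack([l1, l2], meta, y)
        assert np.isfinite(stack.coefs).all()

    def test_accepts_147_candidates(self):
        """A large candidate pool (147 models across families) stacks fine:
        the ridge meta-learner handles wide, collinear meta-features."""
        from geoxai.learners import FAMILIES, MetaFeatures

        rng = np.random.default_rng(11)
        n, k = 300, 147
        y = rng.normal(size=n)
        learners = [
            TunedLearner(FAMILIES[i % len(FAMILIES)], {}, float(i), MemorizeMean(),
                         label=f"c#{i}")
            for i in range(k)
        ]
        meta = MetaFeatures(
            matrix=y[:, None] + rng.normal(0, 1, size=(n, k)),
            fold_assignment=np.zeros(n, dtype=int),
            labels=[t.label for t in learners],
        )
        stack = fit_stack(learners, meta, y, mode="all_models")
        assert len(stack.coefs) == 147
        assert np.isfinite(stack.coefs).all()

    def test_nonnegative_mode(self):
        X, y = _linear_data(n=200)
        l1 = _oracle_learner()
        anti = TunedLearner(
            "penalized-linear", {}, 1.0,
            type("Anti", (BaseEstimator, RegressorMixin), {
                "fit": lambda self, X, y: self,
                "predict": lambda self, X: -(5.0 + 2.0 * np.asarray(X["a"], float)),
            })(),
            label="anti#0",
        )
        meta = oof_predictions([l1, anti], X, y, folds=4, seed=0)
        stack = fit_stack([l1, anti], meta, y, nonnegative=True)
        assert (stack.coefs >= -1e-9).all()
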