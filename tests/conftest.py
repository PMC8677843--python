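import numpy as np
import pandas as pd
import pytest

from geoxai import (
    LatticeSpec,
    contiguity_weights,
    make_lattice,
    make_synthetic_counties,
    simulate_risk_factors,
)


@pytest.fixture(scope="session")
def lattice5():
    return make_lattice(LatticeSpec(5, 5))


@pytest.fixture(scope="session")
def counties_small():
    """20x20 synthetic map with default effects (session-cached)."""
    return make_synthetic_counties(20, 20, seed=11)


@pytest.fixture(scope="session")
def counties_benchmark():
    """40x40 synthetic map — the standard benchmark size (session-cached)."""
    return make_synthetic_counties(40, 40, seed=7)


@pytest.fixture(scope="session")
def queen_self_small(counties_small):
    return contiguity_weights(counties_small, "queen", include_self=True)


def random_lattice_table(nrows, ncols, rng):
    """Lattice with one iid-normal column, for oracle-equivalence checks."""
    table = make_lattice(LatticeSpec(nrows, ncols))
    table["v"] = rng.standard_normal(len(table))
    table["w2"] = rng.standard_normal(len(table))
    return table


@pytest.fixture(scope="session")
def linear_frame():
    """Independent features with a known linear response (n=2000)."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        {
            "a": rng.normal(0, 1, 2000),
            "b": rng.normal(0, 1, 2000),
            "c": rng.normal(0, 1, 2000),
        }
    )
    beta = {"a": 2.0, "b": -1.0, "c": 0.0}
    y = 5.0 + sum(beta[f] * X[f] for f in X.columns)
    return X, y.to_numpy(), beta


class LinearPredictor:
    """Deterministic linear model usable anywhere a fitted model is expected."""

    def __init__(self, intercept, coefs: dict):
        self.intercept = intercept
        self.coefs = coefs

    def predict(self, X):
        out = np.full(len(X), float(self.intercept))
        for f, b in self.coefs.items():
            out += b * np.asarray(X[f], dtype=float)
        return out


@pytest.fixture
def linear_model(linear_frame):
    _, _, beta = linear_frame
    return LinearPredictor(5.0, beta)
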