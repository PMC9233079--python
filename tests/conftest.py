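import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from sklearn.dummy import DummyClassifier, DummyRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from deconfc.synthetic import ToyParams, generate_toy_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def propensity_library():
    """Minimal correctly-specified propensity library for the toy model."""
    return [("glm", LogisticRegression(C=np.inf, max_iter=1000)),
            ("mean", DummyClassifier(strategy="prior"))]


def outcome_library():
    """Minimal correctly-specified outcome library for the toy model."""
    return [("glm", LinearRegression()), ("mean", DummyRegressor())]


def toy_arrays(n: int, seed: int):
    """Toy cohort unpacked into (X, a, delta, y) design arrays."""
    df = generate_toy_cohort(ToyParams(n=n, seed=seed))
    W = df[[c for c in df.columns if c.startswith("W")]].to_numpy()
    X = np.column_stack([df["A"].to_numpy(), W])
    return X, df["A"].to_numpy(), df["delta"].to_numpy(), df["Y"].to_numpy(), df


@pytest.fixture(scope="session")
def toy_550():
    return toy_arrays(550, seed=11)


@pytest.fixture(scope="session")
def toy_5000():
    return toy_arrays(5000, seed=12)
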