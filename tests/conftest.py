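import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppiselect import FeatureTable, SyntheticSpec, generate_table

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted():
    """Balanced table with 4 strong planted features among 20, n=200."""
    table, truth = generate_table(
        SyntheticSpec(
            n_pos=100, n_neg=100, n_features=20, n_informative=4, effect=2.0,
            n_redundant=2, zero_inflation=0.2, seed=11,
        )
    )
    return table, truth


@pytest.fixture()
def tiny_table():
    X = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
    return FeatureTable(["a", "b", "c"], ["f1", "f2"], X, np.array([1, 0, 1]))


def make_table(X, y, prefix="r"):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        [f"{prefix}{i}" for i in range(len(X))],
        [f"f{j}" for j in range(X.shape[1])],
        X,
        np.asarray(y),
    )
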