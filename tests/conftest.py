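import numpy as np
import pytest

from brainvc import ModelData


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_data(
    n=40, B=120, M=2, seed=0, annotated=30, validate=True
) -> ModelData:
    """Small standardized dataset with disjoint binary annotations."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, B))
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Z = np.zeros((B, M))
    for m in range(M):
        Z[m * annotated:(m + 1) * annotated, m] = 1.0
    Y = rng.standard_normal(n)
    Y = (Y - Y.mean()) / Y.std(ddof=1)
    return ModelData(X, Y, Z if M else None, validate=validate)


@pytest.fixture
def small_data():
    return make_data()
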