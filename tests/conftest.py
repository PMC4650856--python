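import numpy as np
import pandas as pd
import pytest

from grnpath.matrix import ExpressionMatrix
from grnpath.simulate import SyntheticConfig, simulate


@pytest.fixture(scope="session")
def dataset():
    """One default synthetic dataset shared across tests."""
    return simulate(SyntheticConfig(rng_seed=7))


@pytest.fixture()
def tiny_matrix():
    """3 features x 4 samples, log2 scale, fixed values."""
    vals = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [4.0, 3.0, 2.0, 1.0],
         [5.0, 5.0, 5.0, 5.0]],
        index=["f1", "f2", "f3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(vals, scale="log2")


def random_matrix(rng, n_features=10, n_samples=6, scale="log2"):
    vals = pd.DataFrame(
        rng.normal(8.0, 1.0, size=(n_features, n_samples)),
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return ExpressionMatrix(vals, scale=scale)
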