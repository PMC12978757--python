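import numpy as np
import pytest

from issbec.data_io import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(values, labels, prefix="f"):
    values = np.asarray(values, float)
    n, d = values.shape
    return DataMatrix(
        values=values,
        feature_names=[f"{prefix}{j}" for j in range(d)],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=np.asarray(labels),
    )


@pytest.fixture
def two_class_matrix(rng):
    """40 samples x 10 features, 2 classes, feature 0 informative."""
    X = rng.normal(size=(40, 10))
    y = np.array(["A"] * 20 + ["B"] * 20)
    X[20:, 0] += 3.0
    return make_matrix(X, y)
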