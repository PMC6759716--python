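import numpy as np
import pytest

from antioxpred import FeatureTable


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_table(X, y, ids=None):
    X = np.asarray(X, dtype=float)
    return FeatureTable(
        sample_ids=ids or [f"s{i}" for i in range(X.shape[0])],
        matrix=X,
        labels=np.asarray(y, dtype=int),
    )


def gaussian_table(rng, n_pos=12, n_neg=24, n_features=10, shift=3.0, n_signal=3):
    """Two Gaussian clouds separated by `shift` along the first features."""
    X = rng.normal(size=(n_pos + n_neg, n_features))
    y = np.array([1] * n_pos + [0] * n_neg)
    X[:n_pos, :n_signal] += shift
    return make_table(X, y)
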