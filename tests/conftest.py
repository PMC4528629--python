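import numpy as np
import pytest

from sparsepc import center_columns, make_spike_model, sample_data


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    """A generic 8 x 5 centered matrix with no planted structure."""
    return center_columns(rng.standard_normal((8, 5)))


@pytest.fixture
def spike_data():
    """Strong-signal spike data: p=200, n=50, alpha=0.8, beta=0.4."""
    model = make_spike_model(200, 0.8, 0.4)
    X = sample_data(model, 50, np.random.default_rng(777))
    return X, model


def rank_one_matrix(rng, n=6, p=4, d=3.0):
    """Exactly rank-one centered-ish matrix d * a b^T with unit a, b."""
    a = rng.standard_normal(n)
    a -= a.mean()
    a /= np.linalg.norm(a)
    b = rng.standard_normal(p)
    b /= np.linalg.norm(b)
    return d * np.outer(a, b), a, b
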