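import numpy as np
import pytest
from scipy.special import expit

from terp.neighborhood import TrainingStats


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def logistic_fixture():
    """Independent-feature neighborhood with a sparse logistic ground truth.

    Returns (design, g, true_support) for a given seed; used wherever a
    generic well-behaved regression fixture is needed.
    """

    def make(seed: int, n_samples: int = 400, n_features: int = 6, k: int = 3):
        r = np.random.default_rng(seed)
        X = r.standard_normal((n_samples, n_features))
        w = np.zeros(n_features)
        idx = r.choice(n_features, k, replace=False)
        w[idx] = r.uniform(0.5, 2.0, k) * r.choice([-1.0, 1.0], k)
        return X, expit(X @ w), tuple(sorted(int(i) for i in idx))

    return make


@pytest.fixture
def simple_stats():
    """Training stats for a 4-feature continuous problem."""
    return TrainingStats(mean=np.zeros(4), sd=np.ones(4))
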