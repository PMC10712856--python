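import numpy as np
import pytest

from gammaglm import Dataset, ModelConfig, PenaltySpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """A tiny clean logistic dataset with a known coefficient vector."""
    n, d = 40, 3
    beta = np.array([1.5, -1.0, 0.0])
    X = rng.standard_normal((n, d))
    from gammaglm import success_prob
    y = rng.binomial(1, success_prob(X, beta))
    return Dataset(X=X, y_observed=y), beta


@pytest.fixture
def default_config():
    return ModelConfig()


def make_config(**kw):
    base = dict(gamma=0.5, threshold=0.0, learning_rate=0.01,
                max_epochs=50, penalty=PenaltySpec("none"))
    base.update(kw)
    return ModelConfig(**base)
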