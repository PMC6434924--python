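import numpy as np
import pytest

from directqr import GumbelParams, RegressionSample, sample_pairs


@pytest.fixture(scope="session")
def gumbel_params():
    return GumbelParams(alpha=1.0)


@pytest.fixture(scope="session")
def gumbel_sample(gumbel_params):
    """One n=100 sample from the bivariate exponential, fixed seed."""
    x, y = sample_pairs(100, gumbel_params, rng=np.random.default_rng(42))
    return RegressionSample(y=y, X=x)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_gumbel_sample(n, seed, alpha=1.0):
    x, y = sample_pairs(n, GumbelParams(alpha=alpha),
                        rng=np.random.default_rng(seed))
    return RegressionSample(y=y, X=x)
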