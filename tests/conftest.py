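import numpy as np
import pytest

from ervphylo import DeletionParams, default_tree


@pytest.fixture(scope="session")
def tree():
    return default_tree()


@pytest.fixture
def exp_params():
    return DeletionParams.exponential(0.12)


@pytest.fixture
def weibull_params():
    return DeletionParams.weibull_inv_scale(0.09, 0.18)


@pytest.fixture
def rng():
    return np.random.default_rng(20160613)
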