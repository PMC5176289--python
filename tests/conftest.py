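import numpy as np
import pytest

from similearn import bayes_core as bc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_world():
    return bc.WorldParams(gamma=0.1, phi=0.9, n_demo=5, sigma=1.0, q=0.75)


@pytest.fixture
def default_rep():
    return bc.CognitiveRep(q_hat=0.75, gamma_hat=0.1, phi_hat=0.9, sigma_hat=1.0)
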