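import numpy as np
import pytest

from psa.operator import OperatorProfile, SyntheticOperator
from psa.policy import PolicyParameters


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def conservative_operator():
    return SyntheticOperator(OperatorProfile.conservative(), seed=7)


@pytest.fixture
def tiny_theta(rng):
    """A small 6-8-4 policy for gradient checks (fast finite differences)."""
    return PolicyParameters.init(rng, input_dim=6, hidden_dim=8, n_actions=4)


@pytest.fixture
def full_theta(rng):
    return PolicyParameters.init(rng)
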