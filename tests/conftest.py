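import numpy as np
import pytest

from sqsim import Box, PotentialParams, RegionPattern


@pytest.fixture
def box20():
    return Box(side_length=20.0)


@pytest.fixture
def thirds():
    return RegionPattern.equal_thirds(1.0, 1.0)


@pytest.fixture
def uniform_pattern():
    return RegionPattern.uniform(1.0)


@pytest.fixture
def pot():
    return PotentialParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
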