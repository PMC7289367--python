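import numpy as np
import pytest

from sipact import MultimerParameters, rectangular


@pytest.fixture(scope="session")
def params36():
    """The reference multimer size used throughout the analysis."""
    return MultimerParameters(36)


@pytest.fixture(scope="session")
def params3():
    """Smallest supported multimer."""
    return MultimerParameters(3)


def constant_profile(tau, duration=1e6):
    """A long rectangular impulse standing in for constant shear."""
    return rectangular(tau, duration)


@pytest.fixture
def rng():
    return np.random.default_rng(20260412)
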