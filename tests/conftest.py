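import numpy as np
import pytest

from spimotion import build_twin_prime
from spimotion.synthetic import demo_scene

TWIN_PRIMES = [(3, 5), (5, 7), (11, 13), (17, 19)]


@pytest.fixture(scope="session")
def S15():
    return build_twin_prime(3, 5)


@pytest.fixture(scope="session")
def S35():
    return build_twin_prime(5, 7)


@pytest.fixture(scope="session")
def S143():
    return build_twin_prime(11, 13)


@pytest.fixture(scope="session")
def S323():
    return build_twin_prime(17, 19)


@pytest.fixture(scope="session")
def S1763():
    return build_twin_prime(41, 43)


@pytest.fixture(scope="session")
def scene1763():
    """Star/blob/bar scene on the 41x43 grid with a 12-px border."""
    img, masks = demo_scene((41, 43), border=12, seed=0)
    return img


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
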