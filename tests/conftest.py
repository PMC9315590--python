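import numpy as np
import pytest

from collateral4d import generate_study, make_protocol


@pytest.fixture(scope="session")
def protocol():
    return make_protocol()


@pytest.fixture(scope="session")
def noiseless_study():
    """A small noiseless poor-collateral study shared across tests."""
    return generate_study("poor", size=(8, 32, 32), seed=11, noise_sigma=0.0)


@pytest.fixture(scope="session")
def noiseless_good_study():
    return generate_study("good", size=(8, 32, 32), seed=12, noise_sigma=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
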