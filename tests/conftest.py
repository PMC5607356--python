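import numpy as np
import pytest

from fibredisp.dmri import DWIProtocol


@pytest.fixture(scope="session")
def protocol():
    """Post-mortem style protocol: 120 directions at b=5000 + 4 near-b0."""
    return DWIProtocol.single_shell()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def add_rician(clean, sigma, rng):
    """Magnitude-detected Gaussian noise."""
    return np.sqrt((clean + rng.normal(0, sigma, clean.shape)) ** 2
                   + rng.normal(0, sigma, clean.shape) ** 2)
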