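import numpy as np
import pytest

from fmindreg import build_foveation_operator


@pytest.fixture(scope="session")
def op55():
    """Default operator: 5x5 patch, rho=2, theta=0."""
    return build_foveation_operator((5, 5), 2.0, 0.0)


@pytest.fixture(scope="session")
def op55_iso():
    return build_foveation_operator((5, 5), 1.0, 0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_volume():
    return np.random.default_rng(7).random((12, 12, 3))
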