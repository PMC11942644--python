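import numpy as np
import pytest

import dexray


@pytest.fixture(scope="session")
def atten():
    return dexray.AttenuationTable()


@pytest.fixture(scope="session")
def phantom():
    """Default chest phantom at the reference 256 px resolution."""
    return dexray.build_chest_phantom(256, 256)


@pytest.fixture(scope="session")
def clean_pair(phantom, atten):
    """Noiseless, motionless dual-energy pair (exact log-linear model)."""
    return dexray.simulate_pair(phantom, atten, noisy=False)


@pytest.fixture(scope="session")
def params(atten):
    return dexray.analytic_params(atten)


@pytest.fixture(scope="session")
def small_phantom():
    """Smaller phantom for the slower Monte-Carlo style checks."""
    return dexray.build_chest_phantom(192, 192)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
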