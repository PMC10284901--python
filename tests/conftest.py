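import numpy as np
import pytest

from memspike import MemristorParams, LIFCircuitParams, ALIFCircuitParams


@pytest.fixture(scope="session")
def mem_params():
    return MemristorParams()


@pytest.fixture(scope="session")
def lif_params():
    return LIFCircuitParams()


@pytest.fixture(scope="session")
def alif_params():
    return ALIFCircuitParams()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
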