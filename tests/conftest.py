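import numpy as np
import pytest

from chemoevolve import ResponseParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


# illustrative kernel parameters (unit-step figures): alpha0 = 10, tau = 5
@pytest.fixture
def adaptive_demo():
    return ResponseParams(alpha0=10.0, beta=5.0, A=-20.0, B=20.0, tau=5.0, strategy="adaptive")


@pytest.fixture
def inverted_demo():
    return ResponseParams(alpha0=10.0, beta=5.0, A=20.0, B=0.0, tau=5.0, strategy="inverted")


@pytest.fixture
def speculator_demo():
    return ResponseParams(alpha0=10.0, beta=5.0, A=20.0, B=-18.0, tau=5.0, strategy="speculator")
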