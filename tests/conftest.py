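import numpy as np
import pytest

from raglscan import aan_ragl_model, make_default_library


@pytest.fixture(scope="session")
def model():
    return aan_ragl_model()


@pytest.fixture(scope="session")
def library():
    return make_default_library()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
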