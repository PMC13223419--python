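import numpy as np
import pytest

from dtswt.synthetic import make_phantom


@pytest.fixture(scope="session")
def ellipse_phantom():
    return make_phantom(256, 256, "ellipses")


@pytest.fixture(scope="session")
def texture_phantom():
    return make_phantom(256, 256, "texture")


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
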