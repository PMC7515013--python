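import numpy as np
import pytest

from animatphi.fixtures import make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def corridor_world():
    return make_fixture("corridor_world")


@pytest.fixture
def open_world():
    return make_fixture("open_world_5x5")


@pytest.fixture
def swap_brain():
    return make_fixture("swap_brain")


@pytest.fixture
def xor_brain():
    return make_fixture("xor_brain")


@pytest.fixture
def copy_brain():
    return make_fixture("copy_brain")


@pytest.fixture
def coin_brain():
    return make_fixture("coin_brain")


@pytest.fixture
def feedback_probe_brain():
    return make_fixture("feedback_probe_brain")
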