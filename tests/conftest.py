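import numpy as np
import pytest

from leksim.params import FemaleParams, IntruderParams, ModelParams
from leksim.scenarios import make_ring_lek


@pytest.fixture
def params():
    return ModelParams()


@pytest.fixture
def iparams():
    return IntruderParams()


@pytest.fixture
def fparams():
    return FemaleParams()


@pytest.fixture
def ring_lek_12():
    state, territories = make_ring_lek(12, spacing=2.0)
    return state, territories


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
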