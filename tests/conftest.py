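import numpy as np
import pytest

from mint32.box import BoxSpec, make_scale_factors


@pytest.fixture
def box50():
    return BoxSpec.cubic(50.0)


@pytest.fixture
def scale50(box50):
    return make_scale_factors(box50)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
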