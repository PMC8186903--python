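import numpy as np
import pytest

from somatomap import (make_block_design, make_cortex_patch, make_phase_design)
from somatomap.hrf import double_gamma_hrf


@pytest.fixture(scope="session")
def hrf():
    return double_gamma_hrf(2.0)


@pytest.fixture(scope="session")
def forward_design():
    return make_phase_design("forward", 20, 5.12, 2.0)


@pytest.fixture(scope="session")
def reverse_design():
    return make_phase_design("reverse", 20, 5.12, 2.0)


@pytest.fixture(scope="session")
def block_design():
    return make_block_design(seed=7)


@pytest.fixture(scope="session")
def patch():
    return make_cortex_patch(grid_shape=(10, 10), seed=3)
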