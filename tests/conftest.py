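import numpy as np
import pytest

from helpers import make_profile, step_profile_grid


@pytest.fixture
def step_profile():
    grid, values = step_profile_grid()
    return make_profile(grid, values)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
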