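import numpy as np
import pytest

from adherence import example_scenario


@pytest.fixture
def s0():
    """Reference scenario: beta=0.8, delta=0.9, p=0.9/0.6, u=1/0, uniform c_max=0.5."""
    return example_scenario()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
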