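import numpy as np
import pytest

import crossfeed as cf


@pytest.fixture
def baseline_params() -> cf.ModelParameters:
    return cf.BASELINE_PARAMETERS


@pytest.fixture
def baseline_scenario() -> cf.Scenario:
    """Reference cocultivation: equal 0.01 inocula, 72 h read every 0.5 h."""
    return cf.Scenario()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
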