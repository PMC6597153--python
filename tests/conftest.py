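import math

import pytest

from forestfronts import ModelParameters, nondimensionalize


@pytest.fixture(scope="session")
def params():
    """Reference (low-savanna) parameter set."""
    return ModelParameters()


@pytest.fixture(scope="session")
def hs_params(params):
    """High savanna-tree-presence regime with short fire return time."""
    return params.with_overrides(r_S=0.13, Q0=0.2, tau=1.0)


@pytest.fixture(scope="session")
def nd(params):
    return nondimensionalize(params)


@pytest.fixture(scope="session")
def no_impact():
    return math.inf
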