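import numpy as np
import pytest
from hypothesis import settings

from cardiodiv.simulate import DivisionErrorRates, simulate_embryo

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def wildtype_embryo():
    return simulate_embryo("wt_000", "wt", DivisionErrorRates(), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
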