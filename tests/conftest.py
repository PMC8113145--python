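import numpy as np
import pytest
from hypothesis import settings

from gliodiff import REFERENCE_CUTOFFS, SequentialCutoffs, gen_fig4_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fig4_table():
    return gen_fig4_fixture()


@pytest.fixture(scope="session")
def ref_cutoffs():
    return SequentialCutoffs(*REFERENCE_CUTOFFS)


@pytest.fixture
def rng():
    return np.random.default_rng(20160201)
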