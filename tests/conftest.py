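import numpy as np
import pytest

from nodemri import phantom


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (52 RG + 42 NRG), generated once."""
    return phantom.generate_cohort(phantom.PhantomSpec(seed=1))


@pytest.fixture()
def small_spec():
    return phantom.PhantomSpec(seed=11, n_rg=6, n_nrg=6)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
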