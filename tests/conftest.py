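import numpy as np
import pytest

from aemeta import McmcConfig, load_oncology


@pytest.fixture(scope="session")
def oncology():
    return load_oncology()


@pytest.fixture(scope="session")
def fast_mcmc():
    """Small-ensemble protocol for unit tests: quick, adequate for medians
    and coarse quantiles."""
    return McmcConfig(chains=1, burn_in=250, thin=1, kept=3000, walkers=10, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
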