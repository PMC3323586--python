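import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dentinsurv.mcmc import McmcConfig
from dentinsurv import synthetic

settings.register_profile(
    "ci", derandomize=True, deadline=None, database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quick_mcmc():
    """Small but convergent chain layout for unit tests."""
    return McmcConfig(chains=2, warmup=500, draws=500)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-truth synthetic cohort shared by read-only tests."""
    return synthetic.simulate_cohort(40, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
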