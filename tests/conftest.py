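import numpy as np
import pytest

from bectoss import SimulationConfig, default_config, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(20130120)


@pytest.fixture(scope="session")
def default_trial():
    """One simulated default trial (24 subjects, fixed seed), shared read-only."""
    return simulate_trial(default_config(seed=42))


@pytest.fixture(scope="session")
def quiet_config():
    """Default design with every noise source switched off."""
    return SimulationConfig(
        bsv_cl=0.0, bsv_v=0.0, bsv_ka=0.0, wsv_cl=0.0, wsv_ka=0.0,
        assay_cv=0.0, time_jitter_sd=0.0, seed=7,
    )
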