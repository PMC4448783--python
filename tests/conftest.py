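import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import thermperf as tp

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One simulated dataset at the default generative parameters."""
    return tp.simulate_dataset(tp.default_params(seed=12345))


@pytest.fixture(scope="session")
def noisefree_params():
    """Parameters with every random source switched off."""
    return tp.default_params().replace(
        re_sd_intercept=0.0, re_sd_at=0.0, re_sd_tt_at=0.0,
        re_sd_tt2_at=0.0, resid_sd=0.0)


@pytest.fixture(scope="session")
def small_dataset():
    """A 5-fish dataset (30 rows) for dense-oracle comparisons."""
    params = tp.default_params(seed=7).replace(n_fish=5, prop_male=0.4)
    return tp.simulate_dataset(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
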