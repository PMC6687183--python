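import pytest
from hypothesis import HealthCheck, settings

import farmbayes as fb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config():
    """4 sites x 10 households x 2 plots x 2 years = 160 records."""
    return fb.default_config_from_table1(households_per_site=10, seed=101)


@pytest.fixture(scope="session")
def small_dataset(tiny_config):
    df, truth = fb.simulate_dataset(tiny_config)
    return df, truth


@pytest.fixture(scope="session")
def medium_dataset():
    """Default full-size layout (1,280 records), fixed seed."""
    df, truth = fb.simulate_dataset(seed=2025)
    return df, truth


@pytest.fixture
def fast_settings():
    return fb.McmcSettings(chains=2, burn_in=200, draws=800, seed=11)
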