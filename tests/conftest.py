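import pytest

from splicesel import SimConfig, simulate_study, synthetic_rate_table


@pytest.fixture(scope="session")
def rates():
    return synthetic_rate_table()


@pytest.fixture(scope="session")
def base_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def study(base_config, rates):
    """One fully simulated study shared across tests (read-only)."""
    return simulate_study(base_config, rates)
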