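import pytest
from hypothesis import settings

from cortmeta import MCMCConfig, builtin_cohort, dataset_from_trials

settings.register_profile("suite", max_examples=50, derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort():
    return builtin_cohort()


@pytest.fixture(scope="session")
def low9(cohort):
    return dataset_from_trials(cohort, "mortality", "low")


@pytest.fixture(scope="session")
def low8(low9):
    return low9.exclude("CSG 1963")


@pytest.fixture(scope="session")
def high5(cohort):
    return dataset_from_trials(cohort, "mortality", "high")


@pytest.fixture(scope="session")
def fast_config():
    """Short chains for structural tests where only rough numerics matter."""
    return MCMCConfig(burn_in=1000, iterations=3000, seed=42)


@pytest.fixture(scope="session")
def medium_config():
    """Chains long enough for quantitative checks at modest tolerance."""
    return MCMCConfig(burn_in=3000, iterations=15000, seed=42)
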