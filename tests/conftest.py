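import numpy as np
import pytest

from milkqtl import fixtures
from milkqtl.simulate import SimulatedCohort, SyntheticConfig, simulate_cohort


@pytest.fixture(scope="session")
def table1():
    return fixtures.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return fixtures.load_fixture("table2")


@pytest.fixture(scope="session")
def table3_matrix():
    return fixtures.load_genotype_fixture("table3")


@pytest.fixture(scope="session")
def table4_matrix():
    return fixtures.load_genotype_fixture("table4")


@pytest.fixture(scope="session")
def clean_cohort() -> SimulatedCohort:
    """Small planted cohort without missingness; shared across tests."""
    config = SyntheticConfig(
        seed=11,
        missing_rate=0.0,
        genome_length=30_000,
        genes_per_genome=10,
        sites_per_category={
            "FIXED_HIGH_VARIABLE_LOW": 5,
            "FIXED_LOW_VARIABLE_HIGH": 4,
            "FIXED_BOTH_CONCORDANT": 2,
            "FIXED_BOTH_DISCORDANT": 2,
            "VARIABLE_BOTH": 3,
        },
    )
    return simulate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
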