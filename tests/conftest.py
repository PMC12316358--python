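import pytest

from sletrends import (
    SimulationConfig,
    build_cohort,
    simulate_registers,
    summarize_exposures,
)


@pytest.fixture(scope="session")
def config():
    """Default study conditions at a moderate cohort size."""
    return SimulationConfig(n_persons=4000, seed=11)


@pytest.fixture(scope="session")
def registers(config):
    return simulate_registers(config)


@pytest.fixture(scope="session")
def cohort_and_exclusions(registers):
    return build_cohort(registers.persons, registers.visits)


@pytest.fixture(scope="session")
def cohort(cohort_and_exclusions):
    return cohort_and_exclusions[0]


@pytest.fixture(scope="session")
def exclusions(cohort_and_exclusions):
    return cohort_and_exclusions[1]


@pytest.fixture(scope="session")
def exposures(cohort, registers):
    return summarize_exposures(cohort, registers.dispensations)
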