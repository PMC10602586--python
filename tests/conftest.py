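import pytest

from apol1sepsis.codes import CodeConfig
from apol1sepsis.config import SimulationConfig
from apol1sepsis.simulate import generate_population


@pytest.fixture(scope="session")
def default_codes():
    return CodeConfig.default()


@pytest.fixture(scope="session")
def population_small():
    """A 1,200-patient noise-free population shared across tests."""
    return generate_population(SimulationConfig(n_patients=1200, seed=123))


@pytest.fixture(scope="session")
def cohort_small(population_small):
    from apol1sepsis.cohort import assemble_cohort

    cohort, attrition = assemble_cohort(
        population_small.patients, population_small.events,
        population_small.labs)
    return cohort, attrition
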