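import numpy as np
import pytest

from basalsim.identification import PKParameters, POPULATION_MEDIANS
from basalsim.virtual_patient import calibrate_baseline, generate_population


@pytest.fixture(scope="session")
def median_pk() -> PKParameters:
    """Degludec PK vector at the identified population medians."""
    return PKParameters(**POPULATION_MEDIANS)


@pytest.fixture(scope="session")
def small_population():
    """Six calibrated virtual subjects shared across trial tests."""
    pop = generate_population(6, seed=4)
    calibrate_baseline(pop, seed=4)
    return pop


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
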