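import numpy as np
import pytest

from perflung.synthetic import (
    OutcomeModel,
    PhantomSpec,
    cohort_tables,
    generate_phantom,
    simulate_cohort,
)

COHORT_SEED = 7
COHORT_N = 200


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom(default_spec):
    """Default phantom with Poisson noise (dose, spect, structures)."""
    return generate_phantom(default_spec)


@pytest.fixture(scope="session")
def phantom_noise_free(default_spec):
    return generate_phantom(default_spec, add_noise=False)


@pytest.fixture(scope="session")
def cohort200():
    """One fixed-seed 200-patient cohort shared by the statistical tests.

    Returns (records, metrics table, visits table).
    """
    records, _ = simulate_cohort(COHORT_N, model=OutcomeModel(), seed=COHORT_SEED)
    metrics, visits = cohort_tables(records)
    return records, metrics, visits


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
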