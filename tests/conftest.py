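import numpy as np
import pytest
from hypothesis import settings

from metalret.synthetic import CohortConfig, generate_cohort, generate_worked_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded 120-subject cohort shared by tests that only read it."""
    records, truth = generate_cohort(CohortConfig(n=120, seed=424))
    return records, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    records, truth = generate_cohort(CohortConfig(n=80, seed=77, noise_sd=0.0))
    return records, truth


@pytest.fixture()
def worked_records():
    return generate_worked_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
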