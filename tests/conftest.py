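import numpy as np
import pytest

from bccost import default_parameters, generate_cohort
from bccost.simulate import simulate_cohort_costs

SEED = 1


@pytest.fixture(scope="session")
def params():
    """The shipped base-case parameterization."""
    return default_parameters()


@pytest.fixture(scope="session")
def full_cohort(params):
    """Full-scale incident cohort (2015 census counts)."""
    return generate_cohort(params, scale=1.0, seed=SEED)


@pytest.fixture(scope="session")
def full_records(params, full_cohort):
    """Realized cost records for the full-scale cohort."""
    return simulate_cohort_costs(full_cohort, params, seed=SEED + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
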