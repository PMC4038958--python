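import numpy as np
import pytest

import scoreinv as si
from scoreinv.fit import FitOptions, fit_ml
from scoreinv.simulation import (
    fixture_model_spec,
    generate_dataset,
    make_fixture,
    two_factor_dgp,
)


@pytest.fixture(scope="session")
def fixture_data():
    """Synthetic five-item Likert table with six ordered age groups."""
    return make_fixture(n=600, seed=11)


@pytest.fixture(scope="session")
def fixture_fit(fixture_data):
    """Restricted (loadings-equal) multi-group fit of the fixture."""
    return fit_ml(fixture_data, fixture_model_spec(), equal=["loadings"])


@pytest.fixture(scope="session")
def dgp():
    return two_factor_dgp()


@pytest.fixture(scope="session")
def sim_fit(dgp):
    """Pooled fit of one null dataset from the two-factor DGP (n=480, m=8)."""
    data = generate_dataset(dgp, None, 480, 8, seed=101)
    return fit_ml(data, dgp.spec, options=FitOptions(restarts=2))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
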