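import numpy as np
import pandas as pd
import pytest

from cpm_shortform.items import SCORED_ITEMS
from cpm_shortform.simulator import CohortSpec, make_cohort


@pytest.fixture(scope="session")
def cohort():
    """One calibrated synthetic cohort (n = 336), shared across tests."""
    return make_cohort(CohortSpec(seed=42))


@pytest.fixture(scope="session")
def scored_responses(cohort):
    """The cohort's response matrix restricted to the 34 scored items."""
    return cohort.responses[list(SCORED_ITEMS)]


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_regression():
    """A small random regression problem (n=40, p=6) for solver oracles."""
    gen = np.random.default_rng(7)
    X = gen.standard_normal((40, 6))
    beta = np.array([2.0, -1.5, 0.0, 0.5, 0.0, 1.0])
    y = X @ beta + 0.5 * gen.standard_normal(40) + 3.0
    return X, y
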