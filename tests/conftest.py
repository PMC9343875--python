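"""Shared fixtures: base parameter set and a seeded virtual population.

The session-scoped cohort runs the full generation chain once (prior → MH
plausible patients → acceptance-rejection against the synthetic target →
NAFLD sub-selection) at a size small enough for the suite but large enough
for stable cohort means.
"""

import numpy as np
import pytest

from steatosim import (
    DEFAULT_FIXTURE_TARGET,
    ParameterPrior,
    PlausibilityBox,
    ar_select,
    default_parameters,
    mh_generate_plausible,
    population_to_frame,
    subselect_nafld,
)


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def plausible_frame():
    prior = ParameterPrior.from_baseline()
    patients = mh_generate_plausible(
        prior, PlausibilityBox(), n_target=2000, seed=20260101
    )
    return population_to_frame(patients)


@pytest.fixture(scope="session")
def vpop(plausible_frame):
    return ar_select(plausible_frame, DEFAULT_FIXTURE_TARGET, seed=714)


@pytest.fixture(scope="session")
def nafld_cohort(vpop):
    cohort = subselect_nafld(vpop, threshold_pct=5.0)
    assert len(cohort) >= 100  # guards cohort-mean stability of downstream tests
    return cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
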