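"""Shared fixtures: synthetic cohorts and their extracted feature tables.

Everything is generated at test time from fixed seeds; no data files ship
with the package.
"""

import warnings

import numpy as np
import pytest

from vowelpap.pipeline import features_from_cohort
from vowelpap.synth import generate_cohort
from vowelpap.types import CohortParams

COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort (18 control + 13 high-risk, with audio)."""
    return generate_cohort(CohortParams(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def cohort_tables(default_cohort):
    """(features, pap) tables of the default cohort; computed once as this
    runs the whole preprocessing + feature-extraction stage."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = features_from_cohort(default_cohort)
    return features, default_cohort.pap_frame()


@pytest.fixture(scope="session")
def small_cohort():
    """A 7-participant cohort for cheap end-to-end checks."""
    return generate_cohort(CohortParams(n_control=4, n_osa=3, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
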