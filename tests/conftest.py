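"""Shared fixtures: small generated cohorts reused across test modules."""

import pytest

from actiphen import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """80-participant cohort with default (reference) parameters."""
    config = CohortConfig(n_participants=80, seed=5)
    daily, questionnaires, truth = generate_cohort(config)
    return config, daily, questionnaires, truth


@pytest.fixture(scope="session")
def full_cohort():
    """Reference-sized cohort (430 participants, ~1250 windows)."""
    config = CohortConfig(seed=1)
    daily, questionnaires, truth = generate_cohort(config)
    return config, daily, questionnaires, truth
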