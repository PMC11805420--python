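"""Shared fixtures: small deterministic cohorts and their example splits."""

import pytest

from moodcast import CohortConfig, generate_cohort, time_split
from moodcast.pipeline import build_examples


@pytest.fixture(scope="session")
def strong_cohort():
    """A small cohort with a strong feature-label signal."""
    cfg = CohortConfig(
        n_participants=12, days_per_participant=120, signal_strength=2.0, seed=11
    )
    sensing, surveys = generate_cohort(cfg)
    return cfg, sensing, surveys


@pytest.fixture(scope="session")
def strong_assignment(strong_cohort):
    _, _, surveys = strong_cohort
    return time_split(surveys)


@pytest.fixture(scope="session")
def strong_split(strong_cohort, strong_assignment):
    """Same-day-horizon examples for the Calm item on the strong cohort."""
    _, sensing, _ = strong_cohort
    return build_examples(sensing, strong_assignment, 0, "Calm")


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort generated with no feature-label signal."""
    cfg = CohortConfig(
        n_participants=10, days_per_participant=90, signal_strength=0.0, seed=5
    )
    sensing, surveys = generate_cohort(cfg)
    return cfg, sensing, surveys
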