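import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mooddyn import (
    FitConfig,
    MoodObservation,
    PopulationSpec,
    Session,
    TrialRecord,
    simulate_cohort,
)
from mooddyn.types import PRIMACY


def make_session(
    outcomes,
    subject_id="s0",
    gamble_flags=None,
    rating_every=2,
    certain=None,
    spread=2.0,
):
    """Hand-rolled session: outcomes given, gambles symmetric around them.

    Ratings are placed every ``rating_every`` trials with value 0.5 (tests
    overwrite values as needed).
    """
    trials = []
    for i, a in enumerate(outcomes, start=1):
        gamble = True if gamble_flags is None else gamble_flags[i - 1]
        if gamble:
            high, low = a, a - spread
            c = certain if certain is not None else 0.5 * (high + low)
            trials.append(TrialRecord(i, high, low, c, True, a))
        else:
            trials.append(TrialRecord(i, a + 1.0, a - 1.0, a, False, a))
    ratings = []
    k = 0
    for t in range(rating_every, len(outcomes) + 1, rating_every):
        k += 1
        ratings.append(MoodObservation(k, t, 0.5))
    return Session(subject_id, "random", trials, ratings)


@pytest.fixture(scope="session")
def tiny_noise_free_cohort():
    """3 primacy-generated subjects on the structured task, no rating noise."""
    pop = PopulationSpec(n_subjects=3, generating_model=PRIMACY, sigma=0.0)
    sessions, truth = simulate_cohort(pop, "structured", seed=42)
    return sessions, truth


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """6 primacy-generated subjects with the default rating noise."""
    pop = PopulationSpec(n_subjects=6, generating_model=PRIMACY)
    sessions, truth = simulate_cohort(pop, "structured", seed=7)
    return sessions, truth


@pytest.fixture
def fast_fit_cfg():
    """Fit settings for small unit-test problems."""
    return FitConfig(restarts=2, seed=0)
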