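"""Shared fixtures: small synthetic cohorts generated once per session."""

import numpy as np
import pytest

from sleepsense.synthetic import CohortSpec, iter_cohort, simulate_observations


@pytest.fixture(scope="session")
def signal_cohort():
    """Two participants x two nights with all four channels."""
    spec = CohortSpec(n_participants=2, n_nights=2, seed=7)
    sessions, diaries, gts = [], [], []
    for session, diary, gt in iter_cohort(spec):
        sessions.append(session)
        diaries.append(diary)
        gts.append(gt)
    return spec, sessions, diaries, gts


@pytest.fixture(scope="session")
def feature_cohort():
    """Feature-level cohort with the default planted label model."""
    spec = CohortSpec(n_participants=8, n_nights=15, seed=19)
    obs, truth = simulate_observations(spec)
    return spec, obs, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
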