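"""Shared fixtures: deterministic profiles, cohorts and small recordings."""

import numpy as np
import pytest

from gaitdmd.synthetic import (
    BASE_MODES,
    CohortSpec,
    Jitter,
    ModeParams,
    PersonProfile,
    WalkwayGeometry,
    make_cohort,
    simulate_recording,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def base_profile():
    """The frozen base walker, deterministic (no jitter, no noise)."""
    modes = [ModeParams(a, f, s) for a, f, s in BASE_MODES]
    return PersonProfile("base", modes, jitter=Jitter(0.0, 0.0, 0.0), noise_sd=0.0)


@pytest.fixture()
def default_profile():
    """The base walker with default step-to-step jitter and noise."""
    modes = [ModeParams(a, f, s) for a, f, s in BASE_MODES]
    return PersonProfile("jittered", modes)


@pytest.fixture(scope="session")
def default_cohort():
    return make_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def small_recording():
    """A 2-pass x 4-step rendered recording with its ground truth."""
    cohort = make_cohort(CohortSpec(seed=1))
    rec, truth = simulate_recording(cohort[0], WalkwayGeometry(),
                                    n_passes=2, steps_per_pass=4, seed=7)
    return rec, truth
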