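"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from pupilnum import features as feat
from pupilnum import stimuli as stim
from pupilnum.preprocess import CleaningParams, process_participant
from pupilnum.simulate import SimParams, simulate_estimates, simulate_participant

CLEAN_KW = dict(
    noise_sd_mm=0.0,
    drift_amplitude_mm=0.0,
    blink_rate_hz=0.0,
    spike_rate_hz=0.0,
    saccade_trial_prob=0.0,
)


def build_cohort(
    n_exp1: int,
    n_exp2: int,
    reps: int,
    params: SimParams,
    seed: int,
    cleaning: CleaningParams = CleaningParams(),
):
    """Trace-level cohort: design, processed trials, features, estimates."""
    designs = []
    if n_exp1:
        designs.append(
            stim.build_design(
                [f"E1P{i + 1:02d}" for i in range(n_exp1)], reps, seed=seed, experiment=1
            )
        )
    if n_exp2:
        designs.append(
            stim.build_design(
                [f"E2P{i + 1:02d}" for i in range(n_exp2)],
                reps,
                seed=seed + 1,
                experiment=2,
            )
        )
    design = pd.concat(designs, ignore_index=True)
    trials = []
    for _, pdesign in design.groupby("participant_id", sort=False):
        sessions = simulate_participant(pdesign, params, seed=seed)
        trials.append(process_participant(sessions, cleaning).trials)
    trials = pd.concat(trials, ignore_index=True)
    features = feat.extract_features(trials)
    estimates = simulate_estimates(design, params, seed=seed)
    return design, trials, features, estimates


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture(scope="session")
def clean_params() -> SimParams:
    """Artifact-free, noise-free generative parameters."""
    return SimParams(**CLEAN_KW)


@pytest.fixture(scope="session")
def small_cohort(default_params):
    """4 participants x 60 trials with default noise and artifacts."""
    return build_cohort(2, 2, reps=3, params=default_params, seed=11)


@pytest.fixture(scope="session")
def one_session(default_params):
    """A single default-parameter session (18 reps, 90 trials, 555 s)."""
    design = stim.build_design(["E1P01"], 18, seed=3, experiment=1)
    sessions = simulate_participant(design, default_params, seed=21)
    return sessions[0]


@pytest.fixture(scope="session")
def participant_sessions(default_params):
    """All four sessions of one participant at a reduced trial count."""
    design = stim.build_design(["E1P01"], 4, seed=5, experiment=1)
    return simulate_participant(design, default_params, seed=13)
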