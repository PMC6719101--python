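"""Shared fixtures.

Simulation-backed fixtures run at a 256 Hz raw rate (a 16x decimation to the
16 Hz working rate) so the suite stays fast; rate-sensitive checks construct
their own full-rate inputs.
"""

import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from cravesense.features import extract_features, features_table
from cravesense.model import SubjectFeatures
from cravesense.preprocess import preprocess_trial
from cravesense.simulate import (SimulationConfig, simulate_study,
                                 simulate_trial_with_truth)

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")

FAST_FS = 256.0


@pytest.fixture(scope="session")
def fast_config():
    return dataclasses.replace(SimulationConfig(), fs_raw=FAST_FS)


@pytest.fixture(scope="session")
def fast_trial(fast_config):
    """One default wash-off trial plus its ground truth."""
    return simulate_trial_with_truth(fast_config, "wash_off", 123)


@pytest.fixture(scope="session")
def fast_processed(fast_trial):
    trial, truth = fast_trial
    return preprocess_trial(trial), truth


@pytest.fixture(scope="session")
def fast_study(fast_config):
    return simulate_study(fast_config, subject_id="S1", seed=11)


@pytest.fixture(scope="session")
def fast_features(fast_study):
    """Tidy feature table for the fast study (108 trials)."""
    return features_table(fast_study)


def make_gaussian_features(seed: int = 0, effect: float = 3.0,
                           session_shift: float = 0.0) -> SubjectFeatures:
    """Synthetic 36x14 per-session feature matrices with one informative
    column (index 3) separating the alternating labels by ``effect`` SDs;
    ``session_shift`` displaces each session's mean of that column."""
    rng = np.random.default_rng(seed)
    X, y = {}, {}
    for s, sid in enumerate(("day1", "day2", "day3")):
        labels = np.tile([0, 1], 18)
        M = rng.normal(size=(36, 14))
        M[:, 3] += effect * labels + session_shift * rng.standard_normal()
        X[sid], y[sid] = M, labels
    return SubjectFeatures(subject_id="synthetic", X=X, y=y)
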