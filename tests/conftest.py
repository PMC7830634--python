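"""Shared fixtures: small synthetic cohorts and derived feature tables.

Session-scoped so the expensive simulation/extraction work is done once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fogstep import CohortConfig, GaitProfile, generate_cohort, generate_trial
from fogstep.pipeline import (
    build_feature_matrix,
    episodes_by_trial,
    labeled_dataset,
    recording_from_synthetic,
)


@pytest.fixture(scope="session")
def clean_trial():
    """Noise-free single trial, 1 Hz cadence, 20 s of walking, no episodes."""
    return generate_trial(
        GaitProfile(cadence_hz=1.0, noise_sd=0.0), duration_s=26.3, seed=7
    )


@pytest.fixture(scope="session")
def clean_recording(clean_trial):
    return recording_from_synthetic(clean_trial)


@pytest.fixture(scope="session")
def noisefree_cohort():
    """Small noise-free cohort without episodes (segmentation oracle)."""
    cfg = CohortConfig(
        n_subjects=4,
        trials_per_subject=1,
        episodes_per_trial=0,
        noise_sd=0.0,
        trial_duration_s=40.0,
        seed=21,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def study_cohort():
    """The default study-sized cohort: 10 subjects x 2 trials, ~3 episodes."""
    trials, manifest = generate_cohort(CohortConfig(seed=2026))
    recordings = [recording_from_synthetic(t) for t in trials]
    return trials, manifest, recordings


@pytest.fixture(scope="session")
def study_features(study_cohort):
    _, _, recordings = study_cohort
    return build_feature_matrix(recordings), episodes_by_trial(recordings)


@pytest.fixture(scope="session")
def prediction_dataset(study_features):
    features, episodes = study_features
    return labeled_dataset(features, episodes, "prediction", 2.0)


@pytest.fixture(scope="session")
def detection_dataset(study_features):
    features, episodes = study_features
    return labeled_dataset(features, episodes, "detection")


@pytest.fixture(scope="session")
def small_prediction_dataset(study_features):
    """A subsampled prediction set for the slower model-level tests."""
    ds = labeled_dataset(*study_features, task="prediction", window_s=2.0)
    rng = np.random.default_rng(5)
    data = ds.data
    keep = rng.choice(len(data), size=min(400, len(data)), replace=False)
    return data.iloc[np.sort(keep)].reset_index(drop=True)
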