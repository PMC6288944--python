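"""Shared fixtures: synthetic walks and cohorts generated at test time."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gaitstage.features import FEATURE_NAMES, extract_features
from gaitstage.preprocess import preprocess_recording
from gaitstage.synthetic import (
    GaitProfile,
    default_stage_templates,
    simulate_cohort,
    simulate_walk,
)


@pytest.fixture(scope="session")
def noiseless_profile():
    """Stage-2-like profile with all sensor noise switched off."""
    base = default_stage_templates()["2"].profile
    return dataclasses.replace(
        base, jitter_sd=0.0, inferred_prob=0.0, trunk_flexion_mean=0.30
    )


@pytest.fixture(scope="session")
def noiseless_walk(noiseless_profile):
    """One noiseless 8-pass corridor walk plus its ground truth."""
    return simulate_walk(
        noiseless_profile, corridor_length=5.0, n_passes=8, seed=11
    )


@pytest.fixture(scope="session")
def processed_noiseless(noiseless_walk):
    recording, _ = noiseless_walk
    return preprocess_recording(recording)


@pytest.fixture(scope="session")
def features_noiseless(processed_noiseless):
    return extract_features(processed_noiseless)


@pytest.fixture(scope="session")
def cohort30():
    """30-subject three-stage cohort at the default study conditions."""
    templates = default_stage_templates()
    return simulate_cohort(
        [templates["1"], templates["2"], templates["3"]], n_per_stage=10, seed=42
    )


@pytest.fixture(scope="session")
def cohort30_features(cohort30):
    rows, labels = {}, []
    for recording, subject, _ in cohort30:
        rows[subject.subject_id] = extract_features(preprocess_recording(recording))
        labels.append(subject.stage_label)
    X = pd.DataFrame(rows).T[list(FEATURE_NAMES)]
    return X, np.array(labels)


@pytest.fixture()
def tiny_profile():
    """Cheap profile for fast unit-level simulations."""
    return GaitProfile(
        step_length=0.6,
        cadence=1.5,
        spin_step_count=4,
        jitter_sd=0.0,
        inferred_prob=0.0,
    )
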