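"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pytest

from fleximu import simulate as sim
from fleximu.evaluate import featurize_dataset
from fleximu.sensor_model import ExerciseLabel


@pytest.fixture(scope="session")
def subject_profile():
    return sim.make_subject_profiles(1, variation=0.1, seed=7)[0]


@pytest.fixture(scope="session")
def correct_session(subject_profile):
    return sim.generate_session(
        subject_profile, ExerciseLabel.ROLLING, anomaly_mode="none",
        duration=30.0, fs=21.0, seed=3)


@pytest.fixture(scope="session")
def rest_session(subject_profile):
    return sim.generate_session(
        subject_profile, ExerciseLabel.ROLLING, anomaly_mode="rest",
        duration=30.0, fs=21.0, seed=4)


@pytest.fixture(scope="session")
def small_dataset():
    """18 short sessions, 3 subjects, 6 anomalous: fast structural tests."""
    sessions, manifest = sim.generate_dataset(
        n_subjects=3, n_sessions=18, n_anomalous=6,
        duration_mean=25.0, duration_spread=3.0, seed=5)
    return sessions, manifest


@pytest.fixture(scope="session")
def small_files(small_dataset):
    sessions, manifest = small_dataset
    return featurize_dataset(sessions, manifest["file_id"].tolist())
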