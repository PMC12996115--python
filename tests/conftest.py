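"""Shared fixtures: simulated sessions, a trained classifier, and a labeled
offline epoch set. Session-scoped because simulation dominates suite runtime."""

import numpy as np
import pytest

from fearloop.calibration import build_calibration_dataset, train_fear_classifier
from fearloop.features import offline_feature_matrix
from fearloop.offline import make_binary_labels
from fearloop.session import (
    EEGBlock,
    HRSeries,
    MarkerStream,
    SessionMeta,
    SessionRecording,
)
from fearloop.simulator import (
    ParticipantParams,
    simulate_labeled_epochs,
    simulate_session,
)


@pytest.fixture(scope="session")
def params():
    return ParticipantParams(seed=1)


@pytest.fixture(scope="session")
def pretest(params):
    """90 s relax + 90 s maximal-stimulus pretest with ground truth."""
    return simulate_session(params, "pretest", seed=100)


@pytest.fixture(scope="session")
def calib_data(pretest):
    session, _ = pretest
    return build_calibration_dataset(session)


@pytest.fixture(scope="session")
def model(calib_data):
    return train_fear_classifier(calib_data)


@pytest.fixture(scope="session")
def offline_dataset(params):
    """60 independent 30-s epochs at levels {1,2,4,5} with binary labels."""
    rng = np.random.default_rng(2)
    levels = rng.choice([1, 2, 4, 5], size=60)
    epochs = simulate_labeled_epochs(params, levels, seed=2)
    X = offline_feature_matrix(epochs)
    labeled = make_binary_labels(epochs.levels, epochs)
    return epochs, X, labeled.binary_label


@pytest.fixture
def tiny_session():
    """Hand-built 10-s, 4-channel session for I/O round-trip checks."""
    rng = np.random.default_rng(7)
    fs = 100.0
    eeg = EEGBlock(["F3", "F4", "C3", "C4"], fs, rng.standard_normal((4, 1000)))
    hr = HRSeries(np.array([2.5, 7.5]), np.array([68.0, 71.0]), 5.0)
    markers = MarkerStream([(6.0, "Spider_Scene"), (6.0, "Spider_Stimulus")])
    meta = SessionMeta("p01", {"STAI_S": 35, "FSQ": 40, "BMIS": 3.0}, ["pilot"])
    return SessionRecording(eeg, hr, markers, meta)
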