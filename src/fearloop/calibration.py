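"""Pretest calibration: build the relax-vs-fear trial set and train the
individualized fear classifier.

The pretest yields two equal-duration phases (neutral scene, then maximal
spider stimulus). Each phase is cut into non-overlapping 500-ms windows, each
window is one trial carrying the 5-value feature vector (4 frontal alpha
asymmetry indices + mean HR). A margin classifier (linear-kernel SVM by
default) is trained on the standardized trials; its signed distance to the
separating hyperplane is the quantity the closed-loop controller thresholds,
with the sign fixed so positive means the fear side regardless of label
encoding. The linear kernel keeps decision values in margin units, which is
what makes fixed +/-0.5 margins meaningful; an RBF kernel is available but
changes the distance scale.

Features are standardized with the calibration-phase scaler and the same
scaler is reused online for scale stability.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from .errors import IncompleteSessionError, InsufficientDataError
from .features import (
    FAA_ALPHA_BAND,
    BandDefinition,
    align_hr_to_eeg,
    calibration_feature_matrix,
    segment_windows,
)
from .montage import FAA_PAIRS
from .preprocess import FilterSpec, preprocess_session
from .session import SessionRecording

__all__ = [
    "CalibrationDataset",
    "FearClassifier",
    "build_calibration_dataset",
    "train_fear_classifier",
    "signed_distance",
    "load_fear_classifier",
]

CALIBRATION_FEATURE_NAMES = [f"FAA_{l}{r}" for l, r in FAA_PAIRS] + ["mean_HR"]


@dataclass
class CalibrationDataset:
    """Trials x 5 feature matrix with 0 = relax / 1 = fear labels and the
    per-feature standardizer fitted on the pooled matrix."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(
        default_factory=lambda: list(CALIBRATION_FEATURE_NAMES)
    )
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X and y are inconsistent")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("calibration features must be finite")
        if self.scaler_mean is None:
            self.scaler_mean = self.X.mean(axis=0)
            sd = self.X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            self.scaler_sd = sd

    def standardized(self) -> np.ndarray:
        return (self.X - self.scaler_mean) / self.scaler_sd


def build_calibration_dataset(
    session: SessionRecording,
    relax_span_s: float = 90.0,
    fear_span_s: float = 90.0,
    window_s: float = 0.5,
    filter_spec: FilterSpec = FilterSpec(),
    pairs=FAA_PAIRS,
    alpha_band: BandDefinition = FAA_ALPHA_BAND,
    preprocess: bool = True,
) -> CalibrationDataset:
    """Cut the pretest into labeled 500-ms trials.

    The relax phase is the ``relax_span_s`` preceding the ``Spider_Scene``
    marker; the fear phase is the ``fear_span_s`` following
    ``Spider_Stimulus``. 90-s phases yield 180 trials per condition.
    """
    scene_times = session.markers.times_of("Spider_Scene")
    stim_times = session.markers.times_of("Spider_Stimulus")
    if not scene_times:
        raise IncompleteSessionError("missing relax/fear boundary: no Spider_Scene")
    if not stim_times:
        raise IncompleteSessionError("missing fear phase: no Spider_Stimulus")
    t_scene, t_stim = scene_times[0], stim_times[0]
    if preprocess:
        clean, _ = preprocess_session(session, filter_spec)
    else:
        clean = session
    eeg = clean.eeg
    hr_aligned = align_hr_to_eeg(clean.hr, eeg)
    fs = eeg.fs_hz

    def phase_trials(t0: float, t1: float) -> np.ndarray:
        i0 = max(0, int(round((t0 - eeg.t0) * fs)))
        i1 = min(eeg.n_samples, int(round((t1 - eeg.t0) * fs)))
        if (i1 - i0) < int(round(window_s * fs)):
            raise InsufficientDataError("phase shorter than one window")
        from .session import EEGBlock

        block = EEGBlock(
            list(eeg.channel_labels), fs, eeg.samples[:, i0:i1], t0=i0 / fs
        )
        epochs = segment_windows(block, window_s)
        return calibration_feature_matrix(
            epochs, hr_aligned, pairs=pairs, alpha_band=alpha_band
        )

    X_relax = phase_trials(t_scene - relax_span_s, t_scene)
    X_fear = phase_trials(t_stim, t_stim + fear_span_s)
    n0, n1 = X_relax.shape[0], X_fear.shape[0]
    if abs(n0 - n1) > 0.05 * max(n0, n1):
        warnings.warn(f"class imbalance: {n0} relax vs {n1} fear trials")
    X = np.vstack([X_relax, X_fear])
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    return CalibrationDataset(X, y)


@dataclass
class FearClassifier:
    """Margin classifier exposing a signed distance-to-boundary contract.

    Positive distances lie on the fear side, negative on the relaxed side;
    the stored sign flips the raw decision value if the label encoding put
    fear on the negative side during training.
    """

    svc: SVC
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    feature_order: list[str]
    sign: float = 1.0
    training_accuracy: float | None = None
    kernel: str = "linear"
    C: float = 1.0

    def signed_distance(self, features: np.ndarray) -> float | np.ndarray:
        """Signed distance to the decision boundary for one feature vector
        (returns a scalar) or a matrix of vectors (returns an array)."""
        f = np.asarray(features, dtype=float)
        single = f.ndim == 1
        f = np.atleast_2d(f)
        if f.shape[1] != len(self.feature_order):
            raise ValueError(
                "feature order mismatch: expected "
                f"{len(self.feature_order)} features, got {f.shape[1]}"
            )
        z = (f - self.scaler_mean) / self.scaler_sd
        d = self.sign * self.svc.decision_function(z)
        return float(d[0]) if single else d

    def save(self, path) -> Path:
        """Persist as a JSON metadata file plus a binary model sidecar."""
        path = Path(path)
        meta = {
            "feature_order": self.feature_order,
            "sign": self.sign,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "training_accuracy": self.training_accuracy,
            "kernel": self.kernel,
            "C": self.C,
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.svc, path.with_suffix(".joblib"))
        return path.with_suffix(".json")


def load_fear_classifier(path) -> FearClassifier:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    svc = joblib.load(path.with_suffix(".joblib"))
    return FearClassifier(
        svc=svc,
        scaler_mean=np.array(meta["scaler_mean"]),
        scaler_sd=np.array(meta["scaler_sd"]),
        feature_order=list(meta["feature_order"]),
        sign=float(meta["sign"]),
        training_accuracy=meta.get("training_accuracy"),
        kernel=meta.get("kernel", "linear"),
        C=meta.get("C", 1.0),
    )


def train_fear_classifier(
    data: CalibrationDataset,
    kernel: str = "linear",
    C: float = 1.0,
    min_trials_per_class: int = 10,
) -> FearClassifier:
    """Fit the individualized fear classifier on standardized trials.

    The decision sign is calibrated so the fear-class mean distance is
    positive.
    """
    classes = np.unique(data.y)
    if classes.size < 2:
        raise ValueError("single-class data: need both relax and fear trials")
    n0, n1 = np.sum(data.y == 0), np.sum(data.y == 1)
    if min(n0, n1) < min_trials_per_class:
        raise ValueError(
            f"need at least {min_trials_per_class} trials per class, got {n0}/{n1}"
        )
    mu0 = data.X[data.y == 0].mean(axis=0)
    mu1 = data.X[data.y == 1].mean(axis=0)
    sd0 = data.X[data.y == 0].std(axis=0)
    sd1 = data.X[data.y == 1].std(axis=0)
    if np.allclose(mu0, mu1) and np.allclose(sd0, sd1):
        raise ValueError("degenerate classes: identical feature distributions")
    Z = data.standardized()
    svc = SVC(kernel=kernel, C=C)
    svc.fit(Z, data.y)
    model = FearClassifier(
        svc=svc,
        scaler_mean=np.asarray(data.scaler_mean),
        scaler_sd=np.asarray(data.scaler_sd),
        feature_order=list(data.feature_names),
        kernel=kernel,
        C=C,
    )
    d_fear = model.signed_distance(data.X[data.y == 1])
    if np.mean(d_fear) < 0:
        model.sign = -1.0
    pred = (np.asarray(model.signed_distance(data.X)) > 0).astype(int)
    model.training_accuracy = float(np.mean(pred == data.y))
    return model


def signed_distance(model: FearClassifier, features: np.ndarray):
    """Functional alias for :meth:`FearClassifier.signed_distance`."""
    return model.signed_distance(features)
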