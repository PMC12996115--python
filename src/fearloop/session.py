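"""Synchronized EEG / heart-rate / marker sessions and their on-disk formats.

A session bundles one participant run: a multichannel EEG block, a low-rate
heart-rate series, an event-marker stream and questionnaire metadata. On load,
all streams are re-referenced to a shared clock whose origin is the first EEG
sample.

Two dialects are supported:

``text``
    A directory holding ``header.json`` (sampling rate, channel order,
    metadata), ``eeg.csv`` (``time`` column + one column per channel, uV),
    ``hr.csv`` (``time,bpm``) and ``markers.csv`` (``time,label``). Channel
    order is authoritative from the header. This dialect is bit-documented so
    ports in other languages interoperate.
``xdf``
    Read-only; requires the optional :mod:`pyxdf` dependency. Stream names are
    configurable via a name map because acquisition software does not
    standardize them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ClockError, IncompleteSessionError

__all__ = [
    "EEGBlock",
    "HRSeries",
    "MarkerStream",
    "SessionMeta",
    "SessionRecording",
    "read_session",
    "write_session",
    "slice_session",
]

#: Valid questionnaire score ranges (instrument minima/maxima).
SCORE_RANGES = {
    "STAI_S": (20, 80),
    "STAI_T": (20, 80),
    "FSQ": (18, 126),
    "BMIS": (-10, 10),
}


@dataclass
class EEGBlock:
    """A channels x time block of EEG in microvolts."""

    channel_labels: list[str]
    fs_hz: float
    samples: np.ndarray  # (n_channels, n_samples)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("label count must equal sample matrix row count")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_hz

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"channel {label!r} not in block") from exc


@dataclass
class HRSeries:
    """Sparse heart-rate series (beats per minute) on its native cadence."""

    times: np.ndarray
    values: np.ndarray
    native_interval_s: float = 5.0
    flags: np.ndarray | None = None  # True where a block value was imputed

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ClockError("clock error: HR timestamps not strictly increasing")

    def validate_range(self, low: float = 20.0, high: float = 250.0) -> None:
        if self.values.size and (
            np.any(self.values <= low) or np.any(self.values >= high)
        ):
            raise ValueError(f"HR values outside physiological range ({low}, {high})")

    def restrict(self, start_s: float, end_s: float) -> "HRSeries":
        keep = (self.times >= start_s) & (self.times < end_s)
        return HRSeries(
            self.times[keep] - start_s,
            self.values[keep],
            self.native_interval_s,
            None if self.flags is None else np.asarray(self.flags)[keep],
        )


@dataclass
class MarkerStream:
    """Timestamped event labels (``Spider_Scene``, ``Level_Change``, ...)."""

    events: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ClockError("clock error: marker timestamps not non-decreasing")
        if any(not lab for _, lab in self.events):
            raise ValueError("marker labels must be non-empty")

    def times_of(self, label: str) -> list[float]:
        return [t for t, lab in self.events if lab == label]

    def first_time(self) -> float | None:
        return self.events[0][0] if self.events else None

    def restrict(self, start_s: float, end_s: float) -> "MarkerStream":
        return MarkerStream(
            [(t - start_s, lab) for t, lab in self.events if start_s <= t < end_s]
        )

    def shifted(self, offset_s: float) -> "MarkerStream":
        return MarkerStream([(t + offset_s, lab) for t, lab in self.events])


@dataclass
class SessionMeta:
    """Participant identity and questionnaire scores consumed as numbers."""

    participant_id: str = "sim"
    scores: dict[str, float] = field(default_factory=dict)
    conditions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, value in self.scores.items():
            key = "BMIS" if name.startswith("BMIS") else name
            if key in SCORE_RANGES:
                lo, hi = SCORE_RANGES[key]
                if not lo <= value <= hi:
                    raise ValueError(
                        f"{name}={value} outside instrument range [{lo}, {hi}]"
                    )


@dataclass
class SessionRecording:
    """One synchronized run: EEG + HR + markers + metadata."""

    eeg: EEGBlock
    hr: HRSeries
    markers: MarkerStream
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        if self.eeg.n_samples == 0:
            raise IncompleteSessionError("incomplete session: empty EEG block")
        lo, hi = self.common_interval()
        if hi <= lo:
            raise ClockError("clock error: streams share no common interval")

    def common_interval(self) -> tuple[float, float]:
        """Overlap of the EEG block and the HR series support."""
        lo = self.eeg.t0
        hi = self.eeg.t0 + self.eeg.duration_s
        if self.hr.times.size:
            lo = max(lo, self.hr.times[0] - self.hr.native_interval_s)
            hi = min(hi, self.hr.times[-1] + self.hr.native_interval_s)
        return lo, hi

    @property
    def duration_s(self) -> float:
        return self.eeg.duration_s


# ---------------------------------------------------------------------------
# text dialect

def _write_text(session: SessionRecording, path: Path) -> Path:
    path.mkdir(parents=True, exist_ok=True)
    header = {
        "format": "fearloop-session",
        "version": 1,
        "fs_hz": session.eeg.fs_hz,
        "channel_labels": list(session.eeg.channel_labels),
        "t0": session.eeg.t0,
        "hr_native_interval_s": session.hr.native_interval_s,
        "meta": {
            "participant_id": session.meta.participant_id,
            "scores": session.meta.scores,
            "conditions": session.meta.conditions,
        },
    }
    (path / "header.json").write_text(json.dumps(header, indent=1))
    eeg = pd.DataFrame(
        session.eeg.samples.T, columns=list(session.eeg.channel_labels)
    )
    eeg.insert(0, "time", session.eeg.times)
    eeg.to_csv(path / "eeg.csv", index=False, float_format="%.10g")
    pd.DataFrame({"time": session.hr.times, "bpm": session.hr.values}).to_csv(
        path / "hr.csv", index=False, float_format="%.10g"
    )
    pd.DataFrame(
        session.markers.events or [], columns=["time", "label"]
    ).to_csv(path / "markers.csv", index=False, float_format="%.10g")
    return path


def _read_text(path: Path) -> SessionRecording:
    for name in ("header.json", "eeg.csv", "hr.csv", "markers.csv"):
        if not (path / name).exists():
            raise IncompleteSessionError(f"incomplete session: missing {name}")
    header = json.loads((path / "header.json").read_text())
    labels = list(header["channel_labels"])
    eeg_df = pd.read_csv(path / "eeg.csv")
    t = eeg_df["time"].to_numpy()
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ClockError("clock error: EEG timestamps not strictly increasing")
    # channel order is authoritative from the header, not file column order
    missing = [lab for lab in labels if lab not in eeg_df.columns]
    if missing:
        raise IncompleteSessionError(f"incomplete session: channels {missing} absent")
    samples = eeg_df[labels].to_numpy().T
    t0 = t[0] if t.size else 0.0
    eeg = EEGBlock(labels, float(header["fs_hz"]), samples, t0=0.0)
    hr_df = pd.read_csv(path / "hr.csv")
    hr = HRSeries(
        hr_df["time"].to_numpy() - t0,
        hr_df["bpm"].to_numpy(),
        float(header.get("hr_native_interval_s", 5.0)),
    )
    mk_df = pd.read_csv(path / "markers.csv")
    markers = MarkerStream(
        [(float(row.time) - t0, str(row.label)) for row in mk_df.itertuples()]
    )
    meta_raw = header.get("meta", {})
    meta = SessionMeta(
        participant_id=meta_raw.get("participant_id", "unknown"),
        scores=dict(meta_raw.get("scores", {})),
        conditions=list(meta_raw.get("conditions", [])),
    )
    return SessionRecording(eeg, hr, markers, meta)


# ---------------------------------------------------------------------------
# xdf dialect (optional dependency)

DEFAULT_STREAM_MAP = {"eeg": "EEG", "hr": "HR", "markers": "Markers"}


def _read_xdf(path: Path, stream_map: dict[str, str] | None = None):
    try:
        import pyxdf
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading XDF sessions requires the optional 'pyxdf' package "
            "(pip install fearloop[xdf]); the text dialect needs no extras"
        ) from exc
    names = {**DEFAULT_STREAM_MAP, **(stream_map or {})}
    streams, _ = pyxdf.load_xdf(str(path))
    by_name = {s["info"]["name"][0]: s for s in streams}

    def pick(kind):
        if names[kind] not in by_name:
            raise IncompleteSessionError(f"incomplete session: no {kind} stream")
        return by_name[names[kind]]

    s_eeg, s_hr, s_mk = pick("eeg"), pick("hr"), pick("markers")
    fs = float(s_eeg["info"]["nominal_srate"][0])
    labels = [
        ch["label"][0]
        for ch in s_eeg["info"]["desc"][0]["channels"][0]["channel"]
    ]
    t = np.asarray(s_eeg["time_stamps"], dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ClockError("clock error: EEG timestamps not strictly increasing")
    t0 = t[0]
    eeg = EEGBlock(labels, fs, np.asarray(s_eeg["time_series"], dtype=float).T, 0.0)
    hr = HRSeries(
        np.asarray(s_hr["time_stamps"], dtype=float) - t0,
        np.asarray(s_hr["time_series"], dtype=float).reshape(-1),
    )
    markers = MarkerStream(
        [
            (float(ts) - t0, str(val[0]))
            for ts, val in zip(s_mk["time_stamps"], s_mk["time_series"])
        ]
    )
    return SessionRecording(eeg, hr, markers)


# ---------------------------------------------------------------------------
# public API

def read_session(
    path, dialect: str = "text", stream_map: dict[str, str] | None = None
) -> SessionRecording:
    """Load a session and normalize its clock to the first EEG sample.

    Parameters
    ----------
    path
        Session directory (``text`` dialect) or ``.xdf`` file (``xdf``).
    dialect
        ``"text"`` or ``"xdf"``.
    stream_map
        Optional XDF stream-name overrides, e.g. ``{"eeg": "BrainVision RDA"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "text":
        return _read_text(path)
    if dialect == "xdf":
        return _read_xdf(path, stream_map)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_session(session: SessionRecording, path, dialect: str = "text") -> Path:
    """Write a session to disk; only the ``text`` dialect is writable."""
    if dialect != "text":
        raise ValueError("only the text dialect supports writing")
    return _write_text(session, Path(path))


def slice_session(
    session: SessionRecording, start_s: float, end_s: float
) -> SessionRecording:
    """Extract ``[start_s, end_s)``, re-referencing times to the slice start.

    The EEG sample count is ``round((end - start) * fs)``; HR samples and
    markers outside the interval are dropped (an empty marker stream is not an
    error).
    """
    if start_s >= end_s:
        raise ValueError("start_s must be before end_s")
    fs = session.eeg.fs_hz
    i0 = int(round((start_s - session.eeg.t0) * fs))
    i1 = int(round((end_s - session.eeg.t0) * fs))
    i0c, i1c = max(i0, 0), min(i1, session.eeg.n_samples)
    if i1c <= i0c:
        raise ValueError("out of range: slice does not intersect session")
    eeg = EEGBlock(
        list(session.eeg.channel_labels),
        fs,
        session.eeg.samples[:, i0c:i1c].copy(),
        t0=0.0,
    )
    return SessionRecording(
        eeg,
        session.hr.restrict(start_s, end_s),
        session.markers.restrict(start_s, end_s),
        replace(session.meta),
    )
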