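"""Closed-loop exposure controller.

Every iteration the most recent 30-s window of EEG and HR is reduced to a
mean signed distance from the fear classifier's boundary and mapped through
fixed margins: a mean below -0.5 (relaxed side) raises the stimulus level, a
mean above +0.5 (fear side) lowers it, anything within the margin keeps it
(boundary values keep, per the strict below/above semantics). Levels saturate
at 1 and 5; each increase introduces a new spider wave and scales spider size
by 10%, and a decrease removes the last wave, so the stimulus template is a
pure function of the current level. A run is 10 iterations.

The subjective 4-point fear rating scores agreement with each action:
an increase is intended for ratings 1-2, a decrease for 3-4, and keeping the
stimulus counts as correct for ratings 2-3.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np

from .calibration import FearClassifier
from .errors import InsufficientDataError
from .features import align_hr_to_eeg, calibration_feature_matrix, segment_windows
from .preprocess import FilterSpec, bandpass_filter, common_average_reference
from .session import SessionRecording, slice_session

__all__ = [
    "Action",
    "StimulusTemplate",
    "ControllerState",
    "DEFAULT_MARGINS",
    "mean_window_distance",
    "decide_action",
    "apply_action",
    "template_for_level",
    "run_adaptive_loop",
    "rating_agreement",
    "write_loop_log",
]

DEFAULT_MARGINS = (-0.5, 0.5)

#: Spider counts per level: (floor, wall, web). Level 1 starts with ten small
#: spiders of the two walking types and one web-net spider; the pretest
#: maximum (level 5) shows 100/100/5.
LEVEL_COUNTS = {
    1: (10, 10, 1),
    2: (20, 20, 2),
    3: (40, 40, 3),
    4: (70, 70, 4),
    5: (100, 100, 5),
}
SIZE_INCREMENT = 1.10  # per level increase


class Action(str, Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    KEEP = "keep"


@dataclass(frozen=True)
class StimulusTemplate:
    """Spider scene content for one stimulus level."""

    level: int
    n_floor: int
    n_wall: int
    n_web: int
    size_scale: float

    def __post_init__(self) -> None:
        if self.level not in range(1, 6):
            raise ValueError("level must be in 1..5")
        if min(self.n_floor, self.n_wall, self.n_web) < 0 or self.size_scale < 1:
            raise ValueError("invalid template")


def template_for_level(level: int, base: StimulusTemplate | None = None) -> StimulusTemplate:
    """Template as a pure function of level: counts from the level table and
    size scaled by 10% per level above 1 (level 5 -> 1.1^4 ~ 1.4641)."""
    if level not in LEVEL_COUNTS:
        raise ValueError("level must be in 1..5")
    floor, wall, web = LEVEL_COUNTS[level]
    base_scale = base.size_scale if base is not None else 1.0
    return StimulusTemplate(
        level, floor, wall, web, base_scale * SIZE_INCREMENT ** (level - 1)
    )


@dataclass(frozen=True)
class HistoryEntry:
    iteration: int
    mean_distance: float
    action: Action
    rating: int | None
    level: int  # level after the action


@dataclass
class ControllerState:
    """Current level, iteration index and the full decision log."""

    level: int = 1
    iteration: int = 0
    history: list[HistoryEntry] = field(default_factory=list)
    margins: tuple[float, float] = DEFAULT_MARGINS
    template: StimulusTemplate = None  # type: ignore[assignment]
    terminated: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.level <= 5:
            raise ValueError("level must be in 1..5")
        if self.template is None:
            self.template = template_for_level(self.level)


def mean_window_distance(
    model: FearClassifier,
    window: SessionRecording,
    sub_window_s: float = 0.5,
    filter_spec: FilterSpec = FilterSpec(),
    preprocess: bool = True,
) -> float:
    """Mean signed distance over the 500-ms sub-windows of one pulled window.

    The window is bandpass-filtered and common-average referenced (the online
    chain; there is no pre-marker interval to baseline against, and the 1-Hz
    high-pass already removes the offset), segmented, featurized, and the
    classifier distances averaged.
    """
    if window.eeg.duration_s < sub_window_s:
        raise InsufficientDataError("window shorter than one sub-window")
    eeg = window.eeg
    if preprocess:
        eeg = common_average_reference(bandpass_filter(eeg, filter_spec))
    hr_aligned = align_hr_to_eeg(window.hr, eeg)
    epochs = segment_windows(eeg, sub_window_s)
    try:
        X = calibration_feature_matrix(epochs, hr_aligned)
    except ValueError as exc:
        raise InsufficientDataError(f"no usable data: {exc}") from exc
    return float(np.mean(model.signed_distance(X)))


def decide_action(
    mean_distance: float, margins: tuple[float, float] = DEFAULT_MARGINS
) -> Action:
    """Map a mean distance through the decision margins.

    Below the lower margin (relaxed side) -> increase; above the upper margin
    (fear side) -> decrease; otherwise (including exactly on a margin) keep.
    """
    if not math.isfinite(mean_distance):
        raise ValueError("mean distance must be finite")
    lo, hi = margins
    if mean_distance < lo:
        return Action.INCREASE
    if mean_distance > hi:
        return Action.DECREASE
    return Action.KEEP


def apply_action(
    state: ControllerState,
    action: Action,
    mean_distance: float = float("nan"),
    rating: int | None = None,
) -> ControllerState:
    """Advance the controller one iteration; levels clamp to [1, 5]."""
    delta = {Action.INCREASE: 1, Action.DECREASE: -1, Action.KEEP: 0}[Action(action)]
    new_level = min(5, max(1, state.level + delta))
    entry = HistoryEntry(state.iteration, mean_distance, Action(action), rating, new_level)
    return replace(
        state,
        level=new_level,
        iteration=state.iteration + 1,
        history=state.history + [entry],
        template=template_for_level(new_level),
    )


def rating_agreement(action: Action, rating: int) -> bool:
    """Whether an action agrees with the participant's 4-point fear rating."""
    if rating not in (1, 2, 3, 4):
        raise ValueError("rating must be an integer in 1..4")
    correct = {
        Action.INCREASE: (1, 2),
        Action.DECREASE: (3, 4),
        Action.KEEP: (2, 3),
    }
    return rating in correct[Action(action)]


def run_adaptive_loop(
    source,
    model: FearClassifier,
    n_iter: int = 10,
    exposure_s: float = 30.0,
    margins: tuple[float, float] = DEFAULT_MARGINS,
    initial_level: int = 1,
    sub_window_s: float = 0.5,
    filter_spec: FilterSpec = FilterSpec(),
) -> ControllerState:
    """Run the closed loop against a streaming source.

    ``source`` is either a participant-like object exposing
    ``next_window(exposure_s)``, ``current_rating()`` and ``set_level(level)``
    (e.g. :class:`fearloop.simulator.VirtualParticipant`) or a prerecorded
    :class:`SessionRecording`, replayed as consecutive ``exposure_s`` windows
    (open loop: nothing is pushed back, ratings are unavailable).

    On source exhaustion the partial log is returned with ``terminated`` set.
    """
    state = ControllerState(level=initial_level, margins=margins)
    streaming = hasattr(source, "next_window")
    for k in range(n_iter):
        try:
            if streaming:
                window = source.next_window(exposure_s)
            else:
                window = slice_session(
                    source, k * exposure_s, (k + 1) * exposure_s
                )
        except (StopIteration, ValueError):
            state.terminated = True
            break
        d = mean_window_distance(
            model, window, sub_window_s, filter_spec=filter_spec
        )
        action = decide_action(d, margins)
        rating = source.current_rating() if streaming else None
        state = apply_action(state, action, mean_distance=d, rating=rating)
        if streaming:
            source.set_level(state.level)
    return state


def write_loop_log(state: ControllerState, path) -> Path:
    """Serialize the decision log as JSON lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for e in state.history:
            fh.write(
                json.dumps(
                    {
                        "iteration": e.iteration,
                        "mean_distance": None
                        if math.isnan(e.mean_distance)
                        else e.mean_distance,
                        "action": e.action.value,
                        "level": e.level,
                        "rating": e.rating,
                    }
                )
                + "\n"
            )
    return path
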