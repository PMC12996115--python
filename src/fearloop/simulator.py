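"""Virtual participant for exercising the closed loop without hardware.

The participant carries a latent fear state in [0, 1] driven by the current
stimulus level through a logistic dose-response with per-exposure habituation:

    fear = logistic(sensitivity * (level - level_midpoint))
           * (1 - habituation_rate) ** n_exposures

The fear state shapes the generated signals in the directions the underlying
phenomenon shows:

* EEG: band-limited oscillators (delta, theta, alpha, beta, gamma) on top of
  1/f noise. Right-frontal alpha amplitude (F4, F8, FC6, FT10) is scaled by
  ``(1 - asymmetry_gain * fear)``, so the measured frontal alpha asymmetry
  expectation is ``2 * ln(1 - asymmetry_gain * fear)`` (power is amplitude
  squared). Frontal theta grows with fear; alpha/beta/gamma are globally
  suppressed.
* HR: baseline + arousal gain * fear, with a bradycardia drop once the
  stimulus level exceeds a threshold ("freezing"), Gaussian jitter, 5-s
  cadence; a raw PPG pulse train can be synthesized at the instantaneous rate.
* Ratings: uniform quantization of fear into the 4-point scale (1 = no fear
  ... 4 = high fear), ties broken downward.

The fear->signal coupling constants (0.3 theta gain, 0.2 fast-band
suppression) are free synthetic choices that mirror observed directions, not
measured effect sizes; they are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import CHANNELS_32, FRONTAL_CHANNELS, RIGHT_FRONTAL_CHANNELS
from .session import (
    EEGBlock,
    HRSeries,
    MarkerStream,
    SessionMeta,
    SessionRecording,
)

__all__ = [
    "ParticipantParams",
    "FearState",
    "fear_value",
    "update_fear_state",
    "quantize_rating",
    "simulate_eeg",
    "simulate_hr",
    "simulate_ppg",
    "simulate_session",
    "VirtualParticipant",
]

#: Oscillator center frequencies (Hz) per band.
BAND_FREQS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 35.0}


@dataclass(frozen=True)
class ParticipantParams:
    """Tunable physiology of the virtual participant."""

    alpha_base: float = 10.0          # baseline alpha amplitude, uV
    asymmetry_gain: float = 0.5       # fractional right-alpha suppression per unit fear
    hr_base: float = 70.0             # resting heart rate, bpm
    hr_arousal_gain: float = 15.0     # bpm per unit fear
    habituation_rate: float = 0.03    # fractional fear decay per exposure
    bradycardia_threshold: int = 4    # stimulus level above which HR drops
    bradycardia_drop: float = 6.0     # bpm per level above the threshold
    sensitivity: float = 2.0          # logistic slope of fear vs stimulus level
    level_midpoint: float = 3.0       # level at which fear = 0.5 (pre-habituation)
    noise_exponent: float = 1.0       # 1/f^x noise slope
    noise_scale: float = 2.0          # 1/f noise standard deviation, uV
    hr_jitter: float = 1.0            # HR measurement jitter, bpm (sd)
    theta_fear_gain: float = 0.3      # frontal theta amplitude gain per unit fear
    fast_band_suppression: float = 0.2  # global alpha/beta/gamma suppression per unit fear
    band_amplitudes: dict = field(
        default_factory=lambda: {"delta": 8.0, "theta": 5.0, "beta": 3.0, "gamma": 1.5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_base <= 0:
            raise ValueError("alpha_base must be positive")
        if not 0 <= self.asymmetry_gain < 1:
            raise ValueError("asymmetry_gain must be in [0, 1)")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")


@dataclass(frozen=True)
class FearState:
    """Latent fear in [0, 1] with the level driving it and the exposure count."""

    value: float
    level: int
    iteration: int


def fear_value(level: float, iteration: int, params: ParticipantParams) -> float:
    """Closed-form fear: logistic in level, geometric habituation in exposure."""
    logistic = 1.0 / (1.0 + np.exp(-params.sensitivity * (level - params.level_midpoint)))
    return float(logistic * (1.0 - params.habituation_rate) ** iteration)


def update_fear_state(
    state: FearState, level: int, params: ParticipantParams
) -> FearState:
    """Advance one exposure: fear is re-evaluated at ``level`` with the
    current habituation depth, then the exposure counter ticks."""
    return FearState(fear_value(level, state.iteration, params), level, state.iteration + 1)


def quantize_rating(fear: float) -> int:
    """Map fear in [0, 1] to the 4-point subjective scale; ties go downward."""
    for rating, upper in ((1, 0.25), (2, 0.5), (3, 0.75)):
        if fear <= upper:
            return rating
    return 4


# ---------------------------------------------------------------------------
# EEG

def _pink_noise(rng: np.random.Generator, n_ch: int, n: int, exponent: float) -> np.ndarray:
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    out = np.fft.irfft(spec * shape, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_eeg(
    fear: float,
    params: ParticipantParams,
    duration_s: float,
    fs: float = 500.0,
    channel_labels=CHANNELS_32,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    t0: float = 0.0,
) -> EEGBlock:
    """Generate a fear-modulated multichannel EEG block (uV).

    Reproducible: the same ``seed`` (or an equally-seeded generator) yields
    bit-identical samples.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    labels = list(channel_labels)
    x = params.noise_scale * _pink_noise(rng, len(labels), n, params.noise_exponent)
    frontal = np.array([lab in FRONTAL_CHANNELS for lab in labels])
    right_frontal = np.array([lab in RIGHT_FRONTAL_CHANNELS for lab in labels])
    fast = 1.0 - params.fast_band_suppression * fear
    for band, freq in BAND_FREQS.items():
        amp = np.full(
            len(labels),
            float(params.band_amplitudes.get(band, params.alpha_base)),
        )
        if band == "alpha":
            amp[:] = params.alpha_base * fast
            amp[right_frontal] *= 1.0 - params.asymmetry_gain * fear
        elif band == "theta":
            amp[frontal] *= 1.0 + params.theta_fear_gain * fear
        elif band in ("beta", "gamma"):
            amp *= fast
        phase = rng.uniform(0.0, 2.0 * np.pi, size=len(labels))
        x += amp[:, None] * np.sin(2.0 * np.pi * freq * t[None, :] + phase[:, None])
    return EEGBlock(labels, fs, x, t0=t0)


# ---------------------------------------------------------------------------
# HR / PPG

def simulate_hr(
    fear,
    params: ParticipantParams,
    duration_s: float,
    level=1,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    cadence_s: float = 5.0,
) -> HRSeries:
    """HR series on the device cadence (default one value per 5 s).

    ``fear`` and ``level`` may be scalars or per-block arrays (one entry per
    cadence block).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    n_blocks = int(round(duration_s / cadence_s))
    times = (np.arange(n_blocks) + 0.5) * cadence_s
    fear = np.broadcast_to(np.asarray(fear, dtype=float), (n_blocks,))
    level = np.broadcast_to(np.asarray(level, dtype=float), (n_blocks,))
    brady = params.bradycardia_drop * np.maximum(
        0.0, level - params.bradycardia_threshold
    )
    values = (
        params.hr_base
        + params.hr_arousal_gain * fear
        - brady
        + params.hr_jitter * rng.standard_normal(n_blocks)
    )
    return HRSeries(times, np.clip(values, 25.0, 245.0), cadence_s)


def simulate_ppg(
    hr_bpm,
    duration_s: float,
    fs: float = 100.0,
    pulse_width_s: float = 0.08,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Synthesize a PPG pulse train at the instantaneous heart rate.

    ``hr_bpm`` is a scalar or a callable ``t -> bpm``. Each beat contributes a
    Gaussian-shaped pulse; optional additive white noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    rate = hr_bpm if callable(hr_bpm) else (lambda t: float(hr_bpm))
    beats = []
    t = 0.0
    while t < duration_s:
        beats.append(t)
        t += 60.0 / max(rate(t), 1e-6)
    tt = np.arange(int(round(duration_s * fs))) / fs
    ppg = np.zeros_like(tt)
    for b in beats:
        lo = np.searchsorted(tt, b - 4 * pulse_width_s)
        hi = np.searchsorted(tt, b + 4 * pulse_width_s)
        ppg[lo:hi] += np.exp(-0.5 * ((tt[lo:hi] - b) / pulse_width_s) ** 2)
    if noise_sd > 0:
        ppg = ppg + noise_sd * rng.standard_normal(ppg.size)
    return ppg


# ---------------------------------------------------------------------------
# whole sessions

def simulate_session(
    params: ParticipantParams,
    protocol: str = "pretest",
    level_schedule=None,
    n_iterations: int = 10,
    exposure_s: float = 30.0,
    relax_s: float = 90.0,
    fear_s: float = 90.0,
    lead_in_s: float = 5.0,
    fs: float = 500.0,
    seed: int | None = None,
    meta: SessionMeta | None = None,
) -> tuple[SessionRecording, pd.DataFrame]:
    """Generate a full session plus its ground-truth trace.

    ``pretest``: ``relax_s`` of neutral scene followed by ``fear_s`` at the
    maximal stimulus; ``Spider_Scene`` and ``Spider_Stimulus`` markers at the
    phase boundary. ``main``: ``lead_in_s`` of neutral lead-in, then
    ``n_iterations`` exposures of ``exposure_s`` each following
    ``level_schedule`` (default: constant level 3), with ``Level_Change``,
    ``Beep`` and ``Rating_<k>`` markers.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    meta = meta or SessionMeta(participant_id="sim")
    if protocol == "pretest":
        fear_max = fear_value(5, 0, params)
        eeg_relax = simulate_eeg(0.0, params, relax_s, fs, rng=rng)
        eeg_fear = simulate_eeg(fear_max, params, fear_s, fs, rng=rng)
        eeg = EEGBlock(
            list(eeg_relax.channel_labels),
            fs,
            np.hstack([eeg_relax.samples, eeg_fear.samples]),
        )
        n_rel = int(round(relax_s / 5.0))
        n_fear = int(round(fear_s / 5.0))
        hr = simulate_hr(
            np.concatenate([np.zeros(n_rel), np.full(n_fear, fear_max)]),
            params,
            relax_s + fear_s,
            level=np.concatenate([np.ones(n_rel), np.full(n_fear, 5.0)]),
            rng=rng,
        )
        markers = MarkerStream(
            [(relax_s, "Spider_Scene"), (relax_s, "Spider_Stimulus")]
        )
        truth = pd.DataFrame(
            {
                "phase": ["relax", "fear"],
                "t0": [0.0, relax_s],
                "t1": [relax_s, relax_s + fear_s],
                "fear": [0.0, fear_max],
                "level": [1, 5],
            }
        )
        return SessionRecording(eeg, hr, markers, meta), truth

    if protocol != "main":
        raise ValueError(f"unknown protocol {protocol!r}")

    levels = (
        [3] * n_iterations if level_schedule is None else list(level_schedule)
    )
    if len(levels) != n_iterations:
        raise ValueError("level_schedule length must equal n_iterations")
    blocks = [simulate_eeg(0.0, params, lead_in_s, fs, rng=rng).samples]
    fear_blocks = [0.0] * int(round(lead_in_s / 5.0))
    level_blocks = [float(levels[0])] * int(round(lead_in_s / 5.0))
    events: list[tuple[float, str]] = [(lead_in_s, "Spider_Stimulus")]
    rows = []
    n_hr_per_iter = int(round(exposure_s / 5.0))
    for k, level in enumerate(levels):
        fear = fear_value(level, k, params)
        blocks.append(simulate_eeg(fear, params, exposure_s, fs, rng=rng).samples)
        fear_blocks += [fear] * n_hr_per_iter
        level_blocks += [float(level)] * n_hr_per_iter
        t_start = lead_in_s + k * exposure_s
        if k > 0 and levels[k] != levels[k - 1]:
            events.append((t_start, "Level_Change"))
        rating = quantize_rating(fear)
        t_end = t_start + exposure_s
        events.append((t_end, "Beep"))
        events.append((t_end, f"Rating_{rating}"))
        rows.append(
            {"iteration": k, "t0": t_start, "level": level, "fear": fear,
             "rating": rating}
        )
    total_s = lead_in_s + n_iterations * exposure_s
    eeg = EEGBlock(list(CHANNELS_32), fs, np.hstack(blocks))
    hr = simulate_hr(
        np.array(fear_blocks), params, total_s, level=np.array(level_blocks), rng=rng
    )
    truth = pd.DataFrame(rows)
    session = SessionRecording(eeg, hr, MarkerStream(sorted(events)), meta)
    return session, truth


def simulate_labeled_epochs(
    params: ParticipantParams,
    levels,
    epoch_s: float = 30.0,
    fs: float = 500.0,
    seed: int | None = None,
):
    """Independent 30-s exposure epochs at the given stimulus levels.

    Each epoch is generated at the closed-form fear of its level (no
    habituation, fresh oscillator phases and noise), which is the offline
    analysis setting: epochs pooled across a run and labeled by level.
    Returns an :class:`fearloop.features.EpochSet` with ``levels`` set.
    """
    from .features import EpochSet

    rng = np.random.default_rng(params.seed if seed is None else seed)
    levels = np.asarray(list(levels), dtype=int)
    data = np.stack(
        [
            simulate_eeg(fear_value(lev, 0, params), params, epoch_s, fs, rng=rng).samples
            for lev in levels
        ]
    )
    starts = np.arange(levels.size) * epoch_s
    return EpochSet(data, list(CHANNELS_32), fs, starts, levels=levels)


class VirtualParticipant:
    """Streaming source for the closed loop: serves 30-s windows at the
    current fear state and accepts level updates pushed back by the
    controller."""

    def __init__(
        self,
        params: ParticipantParams,
        seed: int | None = None,
        initial_level: int = 1,
        fs: float = 500.0,
        max_windows: int | None = None,
    ) -> None:
        self.params = params
        self.fs = fs
        self.rng = np.random.default_rng(params.seed if seed is None else seed)
        self.state = FearState(fear_value(initial_level, 0, params), initial_level, 0)
        self.max_windows = max_windows
        self.windows_served = 0
        self.truth: list[dict] = []

    def next_window(self, exposure_s: float = 30.0) -> SessionRecording:
        """One exposure window of EEG + HR at the current fear state."""
        if self.max_windows is not None and self.windows_served >= self.max_windows:
            raise StopIteration("participant source exhausted")
        eeg = simulate_eeg(
            self.state.value, self.params, exposure_s, self.fs, rng=self.rng
        )
        hr = simulate_hr(
            self.state.value, self.params, exposure_s,
            level=self.state.level, rng=self.rng,
        )
        self.windows_served += 1
        self.truth.append(
            {
                "iteration": self.state.iteration,
                "level": self.state.level,
                "fear": self.state.value,
                "rating": self.current_rating(),
            }
        )
        return SessionRecording(eeg, hr, MarkerStream([]))

    def current_rating(self) -> int:
        return quantize_rating(self.state.value)

    def set_level(self, level: int) -> None:
        """Controller pushes the next stimulus level; habituation ticks."""
        self.state = update_fear_state(self.state, level, self.params)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.truth)


def with_seed(params: ParticipantParams, seed: int) -> ParticipantParams:
    """Convenience: same physiology, different random stream."""
    return replace(params, seed=seed)
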