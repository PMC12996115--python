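"""Spectral and cardiac feature layer shared by calibration, control and
offline analysis.

Two feature vectors are produced:

* the 5-value calibration vector — frontal alpha asymmetry (FAA) from the four
  homologous pairs F3/F4, F7/F8, FC5/FC6, FT9/FT10 plus the mean heart rate in
  the window; FAA uses the 8-13 Hz alpha band;
* the 164-value offline vector — Welch bandpower for 32 channels x 5 bands
  (delta 0-4, theta 4-8, alpha 8-12, beta 12-30, gamma 30-45 Hz; channel-major
  ordering) followed by the four FAA values.

FAA = ln(right alpha power) - ln(left alpha power); negative values indicate
relatively greater right-hemisphere activation because alpha power is
inversely related to cortical activation.

Welch segment length adapts to the window: sub-second calibration windows use
a single full-length Hann taper (500 ms at 500 Hz -> 2 Hz resolution); longer
epochs use 2-s segments with 50% overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, MontageError
from .montage import CHANNELS_32, FAA_PAIRS
from .session import EEGBlock, HRSeries

__all__ = [
    "BandDefinition",
    "STANDARD_BANDS",
    "FAA_ALPHA_BAND",
    "EpochSet",
    "segment_windows",
    "welch_psd",
    "bandpower",
    "faa_index",
    "calibration_features",
    "calibration_feature_matrix",
    "offline_features",
    "offline_feature_names",
    "estimate_hr_from_ppg",
    "align_hr_to_eeg",
]


@dataclass(frozen=True)
class BandDefinition:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError("band requires 0 <= low < high")


#: Topography / offline bands (alpha 8-12 Hz in this context).
STANDARD_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 45.0),
)

#: Alpha band used for the asymmetry index (8-13 Hz).
FAA_ALPHA_BAND = BandDefinition("alpha_faa", 8.0, 13.0)


@dataclass
class EpochSet:
    """Fixed-length segments: (n_epochs, n_channels, n_samples)."""

    data: np.ndarray
    channel_labels: list[str]
    fs_hz: float
    starts_s: np.ndarray
    levels: np.ndarray | None = None  # per-epoch stimulus level, when known

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def window_s(self) -> float:
        return self.data.shape[2] / self.fs_hz


def segment_windows(
    eeg: EEGBlock, window_s: float, overlap_fraction: float = 0.0
) -> EpochSet:
    """Partition a block into fixed windows; a trailing partial window is
    discarded. With overlap ``o`` the epoch count is
    ``floor((T - w) / (w * (1 - o))) + 1``."""
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    n_win = int(round(window_s * eeg.fs_hz))
    if n_win > eeg.n_samples:
        raise InsufficientDataError("window too long for block")
    step = max(1, int(round(n_win * (1 - overlap_fraction))))
    starts = np.arange(0, eeg.n_samples - n_win + 1, step)
    data = np.stack([eeg.samples[:, s : s + n_win] for s in starts])
    return EpochSet(
        data, list(eeg.channel_labels), eeg.fs_hz, eeg.t0 + starts / eeg.fs_hz
    )


def _default_nperseg(n_samples: int, fs: float) -> int:
    if n_samples <= fs:  # sub-second window: single full-length taper
        return n_samples
    return min(n_samples, int(round(2 * fs)))


def welch_psd(
    segment: np.ndarray,
    fs: float,
    seg_len_s: float | None = None,
    overlap_fraction: float = 0.5,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density along the last axis.

    Returns ``(freqs, psd)`` with psd in uV^2/Hz, frequencies spanning 0 to
    the Nyquist rate.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[-1]
    nperseg = (
        _default_nperseg(n, fs) if seg_len_s is None else int(round(seg_len_s * fs))
    )
    if nperseg > n:
        raise InsufficientDataError("segment too short for Welch taper")
    freqs, psd = sps.welch(
        segment,
        fs=fs,
        window=window,
        nperseg=nperseg,
        noverlap=int(nperseg * overlap_fraction),
        axis=-1,
    )
    return freqs, psd


def bandpower(
    freqs: np.ndarray, psd: np.ndarray, band: BandDefinition
) -> np.ndarray:
    """Trapezoid integral of the PSD over ``[low, high)``; non-negative.

    Band edges that fall between grid points are included by linear
    interpolation of the PSD so disjoint bands tile the spectrum additively.
    """
    freqs = np.asarray(freqs)
    lo = max(band.low_hz, freqs[0])
    hi = min(band.high_hz, freqs[-1])
    if hi <= lo:
        raise ValueError("band outside spectrum")
    inner = freqs[(freqs > lo) & (freqs < hi)]
    grid = np.concatenate(([lo], inner, [hi]))
    psd = np.asarray(psd, dtype=float)
    vals = np.stack(
        [np.interp(grid, freqs, p) for p in psd.reshape(-1, freqs.size)]
    )
    power = np.trapezoid(vals, grid, axis=-1)
    return power.reshape(psd.shape[:-1])


def faa_index(left_alpha_power, right_alpha_power):
    """Frontal alpha asymmetry: ln(right) - ln(left).

    Antisymmetric in its arguments and zero at equality; negative values
    reflect relatively greater right-hemisphere activation.
    """
    left = np.asarray(left_alpha_power, dtype=float)
    right = np.asarray(right_alpha_power, dtype=float)
    if np.any(left <= 0) or np.any(right <= 0):
        raise ValueError("invalid power: FAA requires strictly positive powers")
    out = np.log(right) - np.log(left)
    return float(out) if out.ndim == 0 else out


def _pair_indices(labels: list[str], pairs) -> list[tuple[int, int]]:
    idx = []
    for left, right in pairs:
        if left not in labels or right not in labels:
            raise MontageError(f"montage mismatch: pair {left}/{right} absent")
        idx.append((labels.index(left), labels.index(right)))
    return idx


def calibration_features(
    epoch: np.ndarray,
    channel_labels: list[str],
    fs: float,
    hr: HRSeries | np.ndarray,
    pairs=FAA_PAIRS,
    alpha_band: BandDefinition = FAA_ALPHA_BAND,
    epoch_start_s: float = 0.0,
) -> np.ndarray:
    """5-value calibration vector for one window: 4 FAA values + mean HR.

    ``hr`` may be an :class:`HRSeries` (values within the window are averaged;
    if none fall inside, the nearest sample is carried with a warning) or a
    per-sample bpm array aligned to the epoch.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    pair_idx = _pair_indices(channel_labels, pairs)
    freqs, psd = welch_psd(epoch, fs)
    faa = [
        faa_index(
            bandpower(freqs, psd[l], alpha_band), bandpower(freqs, psd[r], alpha_band)
        )
        for l, r in pair_idx
    ]
    window_s = epoch.shape[-1] / fs
    if isinstance(hr, HRSeries):
        inside = (hr.times >= epoch_start_s) & (hr.times < epoch_start_s + window_s)
        if inside.any():
            mean_hr = float(hr.values[inside].mean())
        else:
            if hr.times.size == 0:
                raise InsufficientDataError("no HR data for window")
            j = int(np.argmin(np.abs(hr.times - epoch_start_s)))
            mean_hr = float(hr.values[j])
            warnings.warn("no HR sample in window; nearest value carried")
    else:
        mean_hr = float(np.asarray(hr, dtype=float).mean())
    return np.array(faa + [mean_hr])


def calibration_feature_matrix(
    epochs: EpochSet,
    hr_aligned: np.ndarray,
    pairs=FAA_PAIRS,
    alpha_band: BandDefinition = FAA_ALPHA_BAND,
) -> np.ndarray:
    """Vectorized calibration features for a whole epoch set.

    ``hr_aligned`` is the per-sample bpm series aligned to the block the
    epochs were segmented from (same clock as ``epochs.starts_s``).
    """
    pair_idx = _pair_indices(epochs.channel_labels, pairs)
    chans = sorted({i for lr in pair_idx for i in lr})
    remap = {c: k for k, c in enumerate(chans)}
    freqs, psd = welch_psd(epochs.data[:, chans, :], epochs.fs_hz)
    power = bandpower(freqs, psd, alpha_band)  # (n_epochs, n_pair_channels)
    if np.any(power <= 0):
        raise ValueError("invalid power: zero alpha power in an epoch")
    faa = np.stack(
        [np.log(power[:, remap[r]]) - np.log(power[:, remap[l]]) for l, r in pair_idx],
        axis=1,
    )
    n_win = epochs.data.shape[2]
    fs = epochs.fs_hz
    starts = np.round((epochs.starts_s - epochs.starts_s[0]) * fs).astype(int)
    base = int(round(epochs.starts_s[0] * fs))
    mean_hr = np.array(
        [hr_aligned[base + s : base + s + n_win].mean() for s in starts]
    )
    return np.column_stack([faa, mean_hr])


def offline_feature_names(
    channel_labels=CHANNELS_32, bands=STANDARD_BANDS, pairs=FAA_PAIRS
) -> list[str]:
    """Names in the serialized order: channel-major bandpowers, then FAA."""
    names = [f"{ch}_{b.name}" for ch in channel_labels for b in bands]
    names += [f"FAA_{l}{r}" for l, r in pairs]
    return names


def offline_features(
    epoch: np.ndarray,
    channel_labels: list[str],
    fs: float,
    bands=STANDARD_BANDS,
    pairs=FAA_PAIRS,
    alpha_band: BandDefinition = FAA_ALPHA_BAND,
) -> np.ndarray:
    """164-value offline vector: 32 channels x 5 bands, then 4 FAA values.

    Ordering is channel-major with the band order delta, theta, alpha, beta,
    gamma, followed by the pairs F3/F4, F7/F8, FC5/FC6, FT9/FT10.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[0] != len(channel_labels) or len(channel_labels) != 32:
        raise MontageError("montage mismatch: offline features need 32 channels")
    freqs, psd = welch_psd(epoch, fs)
    bp = np.stack([bandpower(freqs, psd, b) for b in bands], axis=1)  # (ch, band)
    pair_idx = _pair_indices(channel_labels, pairs)
    alpha = bandpower(freqs, psd, alpha_band)
    faa = [faa_index(alpha[l], alpha[r]) for l, r in pair_idx]
    return np.concatenate([bp.reshape(-1), faa])


def offline_feature_matrix(
    epochs: EpochSet,
    bands=STANDARD_BANDS,
    pairs=FAA_PAIRS,
    alpha_band: BandDefinition = FAA_ALPHA_BAND,
) -> np.ndarray:
    """Vectorized :func:`offline_features` over a whole epoch set."""
    if len(epochs.channel_labels) != 32:
        raise MontageError("montage mismatch: offline features need 32 channels")
    freqs, psd = welch_psd(epochs.data, epochs.fs_hz)
    bp = np.stack([bandpower(freqs, psd, b) for b in bands], axis=2)  # (ep, ch, band)
    pair_idx = _pair_indices(epochs.channel_labels, pairs)
    alpha = bandpower(freqs, psd, alpha_band)  # (ep, ch)
    if np.any(alpha <= 0):
        raise ValueError("invalid power: zero alpha power in an epoch")
    faa = np.stack(
        [np.log(alpha[:, r]) - np.log(alpha[:, l]) for l, r in pair_idx], axis=1
    )
    return np.hstack([bp.reshape(epochs.n_epochs, -1), faa])


def estimate_hr_from_ppg(
    ppg: np.ndarray,
    fs: float,
    report_interval_s: float = 5.0,
    min_rate_bpm: float = 30.0,
) -> HRSeries:
    """Heart rate from a raw photoplethysmogram.

    Systolic peaks are detected with a prominence criterion and a refractory
    distance corresponding to ``min_rate_bpm``; each ``report_interval_s``
    block reports 60 / mean inter-peak interval. Blocks with fewer than two
    peaks carry the previous block's value and are flagged.
    """
    ppg = np.asarray(ppg, dtype=float)
    if ppg.size < 10 * fs:
        raise InsufficientDataError("need at least 10 s of PPG")
    # isolate the pulse band before peak picking so broadband noise does not
    # spawn spurious systolic candidates
    sos = sps.butter(3, [0.7, min(8.0, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
    smooth = sps.sosfiltfilt(sos, ppg)
    spread = np.percentile(smooth, 90) - np.percentile(smooth, 10)
    if spread <= 0:
        peaks = np.array([], dtype=int)
    else:
        peaks, _ = sps.find_peaks(
            smooth, prominence=0.3 * spread, distance=int(fs * 60 / 250)
        )
    peak_t = peaks / fs
    n_blocks = int(ppg.size / fs // report_interval_s)
    times, values, flags = [], [], []
    prev = np.nan
    for b in range(n_blocks):
        t0, t1 = b * report_interval_s, (b + 1) * report_interval_s
        inb = peak_t[(peak_t >= t0) & (peak_t < t1)]
        if inb.size >= 2:
            bpm = 60.0 / np.mean(np.diff(inb))
            flagged = False
            prev = bpm
        else:
            bpm, flagged = prev, True
        times.append((t0 + t1) / 2)
        values.append(bpm)
        flags.append(flagged)
    values = np.array(values)
    if np.all(np.isnan(values)):
        values = np.full_like(values, 60.0)  # no peaks anywhere: placeholder
    else:
        # back-fill leading flagged blocks from the first estimated one
        first = np.flatnonzero(~np.isnan(values))[0]
        values[:first] = values[first]
    return HRSeries(
        np.array(times), values, report_interval_s, np.array(flags)
    )


def align_hr_to_eeg(hr: HRSeries, eeg: EEGBlock) -> np.ndarray:
    """Linearly interpolate the HR series onto the EEG time grid; values are
    held constant beyond the HR support."""
    if hr.times.size == 0:
        raise InsufficientDataError("empty HR series")
    return np.interp(eeg.times, hr.times, hr.values)
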