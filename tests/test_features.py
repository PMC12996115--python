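"""Feature layer: windowing, Welch spectra, band powers, FAA, HR features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearloop.errors import InsufficientDataError, MontageError
from fearloop.features import (
    FAA_ALPHA_BAND,
    STANDARD_BANDS,
    BandDefinition,
    align_hr_to_eeg,
    bandpower,
    calibration_features,
    estimate_hr_from_ppg,
    faa_index,
    offline_features,
    segment_windows,
    welch_psd,
)
from fearloop.montage import CHANNELS_32, FAA_PAIRS
from fearloop.session import EEGBlock, HRSeries
from fearloop.simulator import ParticipantParams, simulate_eeg, simulate_ppg

FS = 500.0


def block(duration_s, n_ch=2, fill=0.0):
    n = int(duration_s * FS)
    return EEGBlock(
        [f"ch{i}" for i in range(n_ch)], FS, np.full((n_ch, n), fill)
    )


class TestSegmentation:
    @pytest.mark.parametrize(
        "duration,window,overlap,expected",
        [
            (90.0, 0.5, 0.0, 180),  # the calibration trial count
            (30.0, 30.0, 0.0, 1),
            (10.0, 4.0, 0.5, 4),
            (10.0, 3.0, 0.0, 3),  # trailing partial window discarded
        ],
    )
    def test_epoch_counts(self, duration, window, overlap, expected):
        epochs = segment_windows(block(duration), window, overlap)
        assert epochs.n_epochs == expected

    def test_window_longer_than_data(self):
        with pytest.raises(InsufficientDataError):
            segment_windows(block(1.0), 2.0)


class TestWelch:
    def test_peak_at_sinusoid_frequency(self):
        t = np.arange(int(4 * FS)) / FS
        freqs, psd = welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        assert freqs[np.argmax(psd)] == pytest.approx(10.0, abs=freqs[1])

    def test_power_scales_quadratically_with_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(int(20 * FS))
        f, p1 = welch_psd(x, FS)
        _, p2 = welch_psd(2 * x, FS)
        ratio = np.trapezoid(p2, f) / np.trapezoid(p1, f)
        assert ratio == pytest.approx(4.0, rel=0.10)

    def test_zero_signal(self):
        _, psd = welch_psd(np.zeros(int(2 * FS)), FS)
        assert np.all(psd == 0)

    def test_too_short_segment(self):
        with pytest.raises(InsufficientDataError):
            welch_psd(np.zeros(100), FS, seg_len_s=1.0)


class TestBandpower:
    def test_alpha_captures_sinusoid(self):
        t = np.arange(int(8 * FS)) / FS
        freqs, psd = welch_psd(np.sin(2 * np.pi * 10 * t), FS)
        alpha = bandpower(freqs, psd, BandDefinition("alpha", 8, 12))
        total = bandpower(freqs, psd, BandDefinition("all", 0, FS / 2))
        assert alpha >= 0.9 * total

    def test_disjoint_bands_are_additive(self):
        rng = np.random.default_rng(1)
        freqs, psd = welch_psd(rng.standard_normal(int(10 * FS)), FS)
        total = bandpower(freqs, psd, BandDefinition("all", 0, 45))
        parts = sum(bandpower(freqs, psd, b) for b in STANDARD_BANDS)
        assert parts <= total + 1e-9
        assert parts == pytest.approx(total, rel=1e-6)

    def test_zero_spectrum(self):
        freqs = np.linspace(0, 250, 126)
        assert bandpower(freqs, np.zeros(126), STANDARD_BANDS[2]) == 0

    def test_band_outside_spectrum(self):
        freqs = np.linspace(0, 20, 21)
        with pytest.raises(ValueError):
            bandpower(freqs, np.ones(21), BandDefinition("x", 30, 45))


class TestFAA:
    def test_equal_powers_give_zero(self):
        assert faa_index(3.7, 3.7) == 0.0

    def test_ln2_example(self):
        assert faa_index(1.0, 2.0) == pytest.approx(np.log(2), abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        left=st.floats(1e-6, 1e6), right=st.floats(1e-6, 1e6)
    )
    def test_antisymmetry(self, left, right):
        assert faa_index(left, right) == pytest.approx(
            -faa_index(right, left), abs=1e-9
        )

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            faa_index(0.0, 1.0)


class TestCalibrationVector:
    def test_symmetric_epoch_yields_zero_faa_and_hr_mean(self):
        t = np.arange(250) / FS
        sig = np.sin(2 * np.pi * 10 * t)
        epoch = np.tile(sig, (32, 1))
        hr = HRSeries(np.array([0.1, 0.3]), np.array([72.0, 72.0]), 0.2)
        v = calibration_features(epoch, list(CHANNELS_32), FS, hr)
        assert v.shape == (5,)
        np.testing.assert_allclose(v[:4], 0.0, atol=1e-9)
        assert v[4] == 72.0

    def test_missing_pair_channel(self):
        with pytest.raises(MontageError):
            calibration_features(
                np.ones((4, 250)), ["F3", "F4", "F7", "F8"], FS,
                HRSeries(np.array([0.1]), np.array([70.0])),
            )


class TestOfflineVector:
    def test_feature_counts(self, params):
        eeg = simulate_eeg(0.5, params, 30.0, seed=3)
        v = offline_features(eeg.samples, list(CHANNELS_32), FS)
        assert v.shape == (164,)
        assert np.all(v[:160] >= 0)  # the 160 bandpowers

    def test_zero_epoch_rejected(self):
        with pytest.raises(ValueError):
            offline_features(np.zeros((32, int(30 * FS))), list(CHANNELS_32), FS)

    def test_wrong_channel_count(self):
        with pytest.raises(MontageError):
            offline_features(np.ones((8, 1000)), [f"c{i}" for i in range(8)], FS)


class TestPPG:
    def test_clean_72_bpm_recovered(self):
        ppg = simulate_ppg(72.0, 60.0, fs=100.0)
        hr = estimate_hr_from_ppg(ppg, 100.0)
        assert np.all(np.abs(hr.values - 72.0) <= 1.0)
        assert not hr.flags.any()

    def test_noisy_60_bpm_within_2(self):
        rng = np.random.default_rng(3)
        ppg = simulate_ppg(60.0, 60.0, fs=100.0)
        noise_sd = ppg.std() / 10 ** (10 / 20)  # SNR 10 dB
        hr = estimate_hr_from_ppg(ppg + noise_sd * rng.standard_normal(ppg.size), 100.0)
        assert np.all(np.abs(hr.values - 60.0) <= 2.0)

    def test_flatline_flagged(self):
        hr = estimate_hr_from_ppg(np.zeros(6000), 100.0)
        assert hr.flags.all()

    def test_too_short(self):
        with pytest.raises(InsufficientDataError):
            estimate_hr_from_ppg(np.zeros(100), 100.0)


class TestHRAlignment:
    def test_constant_series(self):
        hr = HRSeries(np.array([2.5, 7.5]), np.array([70.0, 70.0]))
        out = align_hr_to_eeg(hr, block(10.0))
        np.testing.assert_allclose(out, 70.0)

    def test_linear_midpoint(self):
        hr = HRSeries(np.array([0.0, 5.0]), np.array([60.0, 70.0]))
        out = align_hr_to_eeg(hr, block(10.0))
        assert out[int(2.5 * FS)] == pytest.approx(65.0, abs=0.02)

    def test_exact_at_native_timestamps(self):
        rng = np.random.default_rng(4)
        times = np.arange(10) * 5.0 + 2.5
        values = 70 + np.cumsum(rng.standard_normal(10))
        hr = HRSeries(times, values)
        out = align_hr_to_eeg(hr, block(60.0))
        for t, v in zip(times, values):
            assert out[int(t * FS)] == pytest.approx(v, abs=1e-6)


class TestAsymmetryMonotonicity:
    def test_mean_faa_decreases_with_asymmetry_gain(self):
        """Raising the simulator's right-alpha suppression must push the
        measured mean FAA further negative."""
        means = []
        for gain in (0.1, 0.3, 0.5):
            p = ParticipantParams(seed=9, asymmetry_gain=gain)
            eeg = simulate_eeg(1.0, p, 50.0, seed=9)
            epochs = segment_windows(eeg, 2.0)
            freqs, psd = welch_psd(epochs.data, FS)
            power = bandpower(freqs, psd, FAA_ALPHA_BAND)
            labels = list(eeg.channel_labels)
            faa = np.mean(
                [
                    np.log(power[:, labels.index(r)]) - np.log(power[:, labels.index(l)])
                    for l, r in FAA_PAIRS
                ]
            )
            means.append(faa)
        assert means[0] > means[1] > means[2]
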