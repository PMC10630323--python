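"""Wavelet filtering, envelope detrending and segmentation contracts."""

import numpy as np
import pandas as pd
import pytest
import pywt

from ppgvitals.core import PeakSet, Signal
from ppgvitals.preprocess import SegmentDataset, WaveletSpec, detrend, segment, wavelet_filter


def _band_energy(x, fs, f0, half_width=0.3):
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    band = (freqs >= f0 - half_width) & (freqs <= f0 + half_width)
    return spec[band].sum()


class TestWaveletFilter:
    def test_zero_in_zero_out(self):
        out = wavelet_filter(Signal(np.zeros(512), fs=125))
        assert np.all(out.data == 0)
        assert out.n_samples == 512

    def test_baseline_removed_cardiac_band_kept(self):
        fs = 125
        t = np.arange(fs * 60) / fs
        x = np.sin(2 * np.pi * 0.05 * t) + 0.5 * np.sin(2 * np.pi * 2.0 * t)
        out = wavelet_filter(Signal(x, fs)).data
        drop_low = 10 * np.log10(
            _band_energy(x, fs, 0.05, 0.04) / max(_band_energy(out, fs, 0.05, 0.04), 1e-30)
        )
        drop_card = 10 * np.log10(_band_energy(x, fs, 2.0) / _band_energy(out, fs, 2.0))
        assert drop_low > 20
        assert abs(drop_card) < 3

    def test_equals_band_summation_oracle(self, rng):
        # independent decomposition: reconstruct each kept detail band alone
        x = rng.normal(size=700)
        spec = WaveletSpec()
        out = wavelet_filter(Signal(x, fs=125), spec).data
        coeffs = pywt.wavedec(x, spec.family, level=spec.levels, mode="symmetric")
        total = np.zeros_like(x)
        for keep in range(3, spec.levels + 1):  # detail bands 3..5
            parts = [np.zeros_like(c) for c in coeffs]
            parts[-keep] = coeffs[-keep]
            total += pywt.waverec(parts, spec.family, mode="symmetric")[: len(x)]
        assert np.max(np.abs(out - total)) < 1e-8

    def test_linearity(self, rng):
        x = rng.normal(size=600)
        y = rng.normal(size=600)
        fa = wavelet_filter(Signal(2.0 * x + 3.0 * y, fs=125)).data
        fb = 2.0 * wavelet_filter(Signal(x, fs=125)).data + 3.0 * wavelet_filter(
            Signal(y, fs=125)
        ).data
        assert np.max(np.abs(fa - fb)) < 1e-9

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            wavelet_filter(Signal(np.zeros(16), fs=125))


def _sine_fiducials(n=1000, period=100):
    t = np.arange(n)
    x = np.sin(2 * np.pi * t / period)
    peaks = np.arange(period // 4, n, period)
    valleys = np.arange(3 * period // 4, n, period)
    return x, PeakSet(peaks), PeakSet(valleys, "valley")


class TestDetrend:
    def test_sinusoid_maps_extrema_to_half(self):
        x, peaks, valleys = _sine_fiducials()
        y = detrend(Signal(x, fs=100), peaks, valleys).data
        assert np.max(np.abs(y[peaks.indices] - 0.5)) < 1e-6
        assert np.max(np.abs(y[valleys.indices] + 0.5)) < 1e-6

    def test_range_is_half_centered(self):
        # magnitude in [0, 1] before the 0.5 offset => [-0.5, 0.5] after
        x, peaks, valleys = _sine_fiducials()
        y = detrend(Signal(x, fs=100), peaks, valleys).data
        lo, hi = peaks.indices[0], valleys.indices[-1]
        inner = y[lo:hi]
        assert inner.min() >= -0.5 - 0.05
        assert inner.max() <= 0.5 + 0.05

    def test_linear_drift_removed(self):
        x, peaks, valleys = _sine_fiducials()
        drifted = x + 0.01 * np.arange(len(x))
        y = detrend(Signal(drifted, fs=100), peaks, valleys).data
        lo, hi = peaks.indices[0], valleys.indices[-1]
        slope = np.polyfit(np.arange(lo, hi), y[lo:hi], 1)[0]
        assert abs(slope) < 1e-4

    def test_affine_invariance(self):
        x, peaks, valleys = _sine_fiducials()
        y1 = detrend(Signal(x, fs=100), peaks, valleys).data
        y2 = detrend(Signal(7.0 * x + 11.0, fs=100), peaks, valleys).data
        assert np.max(np.abs(y1 - y2)) < 1e-6

    def test_degenerate_envelope_names_offending_index(self):
        x = np.zeros(200)
        peaks = PeakSet(np.array([50, 150]))
        valleys = PeakSet(np.array([20, 100, 180]), "valley")
        with pytest.raises(ValueError, match="sample 0"):
            detrend(Signal(x, fs=100), peaks, valleys)

    def test_needs_two_of_each_fiducial(self):
        x = np.sin(np.linspace(0, 20, 500))
        with pytest.raises(ValueError, match="at least 2"):
            detrend(Signal(x, fs=100), PeakSet(np.array([100])), PeakSet(np.array([50, 300]), "valley"))


def _labels(T, value=None, rng=None):
    if value is not None:
        data = {"hr": np.full(T, value)}
    else:
        data = {"hr": rng.uniform(60, 100, T)}
    return pd.DataFrame(data)


class TestSegment:
    def test_single_window_label_is_mean_of_ten(self, rng):
        fs = 10
        sig = Signal(rng.normal(size=fs * 10), fs=fs)
        labels = _labels(10, rng=rng)
        ds = segment(sig, labels, w_s=10)
        assert len(ds) == 1
        assert ds.labels[0, 0] == pytest.approx(labels["hr"].mean())

    def test_count_formula_matches_enumeration(self, rng):
        fs, T, w_s = 5, 300, 20
        sig = Signal(rng.normal(size=fs * T), fs=fs)
        ds = segment(sig, _labels(T, rng=rng), w_s=w_s)
        assert len(ds) == 281  # floor(T - w_s) + 1
        # explicit enumeration oracle
        count = sum(
            1
            for start in range(0, T)
            if start + w_s <= T
        )
        assert len(ds) == count

    def test_constant_labels_propagate(self, rng):
        fs = 10
        sig = Signal(rng.normal(size=fs * 30), fs=fs)
        ds = segment(sig, _labels(30, value=67.0), w_s=10)
        assert np.all(ds.labels == 67.0)

    def test_window_longer_than_signal_rejected(self, rng):
        sig = Signal(rng.normal(size=50), fs=10)
        with pytest.raises(ValueError, match="exceeds"):
            segment(sig, _labels(5, value=70.0), w_s=10)

    def test_non_integral_window_samples_rejected(self, rng):
        sig = Signal(rng.normal(size=500), fs=12.5)
        with pytest.raises(ValueError, match="integral"):
            segment(sig, _labels(40, value=70.0), w_s=10.01)

    def test_label_mass_preserved_at_fine_stride(self, rng):
        fs, T, w_s = 5, 40, 4
        sig = Signal(rng.normal(size=fs * T), fs=fs)
        labels = _labels(T, rng=rng)
        ds = segment(sig, labels, w_s=w_s, stride=1.0)
        # windowed means average back to close to the stream mean
        assert ds.labels.mean() == pytest.approx(labels["hr"].to_numpy()[1:-1].mean(), rel=0.02)

    def test_save_load_round_trip(self, tmp_path, rng):
        fs = 10
        sig = Signal(rng.normal(size=(fs * 20, 2)), fs=fs)
        labels = _labels(20, rng=rng)
        ds = segment(sig, labels, w_s=5, subject="s1")
        path = tmp_path / "ds.npz"
        ds.save(path)
        back = SegmentDataset.load(path)
        np.testing.assert_allclose(back.segments, ds.segments)
        np.testing.assert_allclose(back.labels, ds.labels)
        assert back.vital_names == ds.vital_names
        assert list(back.subjects) == list(ds.subjects)
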