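"""Preprocessing: mute-window interpolation, filtering, resampling, epoching."""

import numpy as np
import pandas as pd
import pytest

from stncc import (
    ContinuousEEG, FilterSpec, epoch, interpolate_mute_window,
    reject_epochs, resample, subtract_tms_only, windowed_sinc_filter,
)


def _eeg(data, rate, events=None):
    ev = events if events is not None else pd.DataFrame(
        columns=["type", "time_ms", "trial"])
    labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    return ContinuousEEG(data=data, rate=rate, channel_labels=labels, events=ev)


class TestMuteWindowInterpolation:
    def test_zero_signal_stays_zero(self):
        out = interpolate_mute_window(np.zeros(1000), 5000.0, 100.0)
        assert not out.any()

    def test_exact_on_cubic(self):
        rate = 5000.0
        t = np.arange(2000) / rate * 1000.0
        sig = 0.5 * (t - 200.0) ** 3 - 2.0 * t ** 2 + t - 7.0
        out = interpolate_mute_window(sig, rate, 200.0)
        rel = np.abs(out - sig).max() / np.abs(sig).max()
        assert rel < 1e-9

    def test_outside_window_bit_identical(self, rng):
        rate = 1000.0
        sig = rng.standard_normal(500)
        out = interpolate_mute_window(sig, rate, 250.0, window_ms=15,
                                      pre_samples=3, anchor_ms=10)
        i0 = 250 - 3
        i1 = i0 + 15
        np.testing.assert_array_equal(out[:i0], sig[:i0])
        np.testing.assert_array_equal(out[i1:], sig[i1:])

    def test_matches_normal_equations_oracle(self, rng):
        rate = 1000.0
        sig = rng.standard_normal(400)
        pulse, window, pre, anchor = 200.0, 15, 3, 10
        out = interpolate_mute_window(sig, rate, pulse, window, pre, anchor)
        i0, n_mute, n_anc = 200 - pre, window, anchor
        i1 = i0 + n_mute
        idx = np.r_[i0 - n_anc:i0, i1:i1 + n_anc].astype(float)
        # independent least-squares fit via explicit normal equations
        # (abscissa centred for conditioning; still a distinct solver path)
        c = idx.mean()
        X = np.vander(idx - c, 4)
        beta = np.linalg.solve(X.T @ X, X.T @ sig[idx.astype(int)])
        expect = np.vander(np.arange(i0, i1, dtype=float) - c, 4) @ beta
        np.testing.assert_allclose(out[i0:i1], expect, atol=1e-9)

    def test_window_at_edge_raises(self):
        with pytest.raises(ValueError, match="inside the signal"):
            interpolate_mute_window(np.zeros(100), 1000.0, 2.0)

    def test_short_anchor_raises(self):
        with pytest.raises(ValueError, match="anchor"):
            interpolate_mute_window(np.zeros(1000), 1000.0, 500.0,
                                    anchor_ms=1.0)


class TestWindowedSincFilter:
    rate = 250.0

    def test_dc_preserved_by_lowpass(self):
        spec = FilterSpec(highpass_hz=None, lowpass_hz=40.0)
        t = np.arange(int(20 * self.rate))
        out = windowed_sinc_filter(np.ones_like(t, dtype=float), self.rate, spec)
        mid = out[len(t) // 4: -len(t) // 4]
        assert np.abs(mid - 1.0).max() < 1e-3

    def test_half_amplitude_at_cutoff(self):
        spec = FilterSpec(highpass_hz=None, lowpass_hz=40.0)
        t = np.arange(int(60 * self.rate)) / self.rate
        x = np.sin(2 * np.pi * 40.0 * t)
        y = windowed_sinc_filter(x, self.rate, spec)
        mid = slice(int(20 * self.rate), int(40 * self.rate))
        assert y[mid].std() / x[mid].std() == pytest.approx(0.5, abs=0.02)

    def test_stopband_attenuation(self):
        spec = FilterSpec(highpass_hz=None, lowpass_hz=40.0)
        t = np.arange(int(60 * self.rate)) / self.rate
        x = np.sin(2 * np.pi * 100.0 * t)
        y = windowed_sinc_filter(x, self.rate, spec)
        mid = slice(int(20 * self.rate), int(40 * self.rate))
        assert y[mid].std() / x[mid].std() < 0.01

    def test_cutoff_at_or_above_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            windowed_sinc_filter(np.zeros(100), self.rate,
                                 FilterSpec(highpass_hz=None, lowpass_hz=125.0))

    def test_linearity(self, rng):
        spec = FilterSpec(highpass_hz=None, lowpass_hz=40.0,
                          transition_bw_hz=10.0)
        t = np.arange(2000) / self.rate
        a = np.sin(2 * np.pi * 5 * t)
        b = np.sin(2 * np.pi * 17 * t + 0.3)
        ya = windowed_sinc_filter(a, self.rate, spec)
        yb = windowed_sinc_filter(b, self.rate, spec)
        yab = windowed_sinc_filter(a + b, self.rate, spec)
        np.testing.assert_allclose(yab, ya + yb, atol=1e-6 * np.abs(ya + yb).max())

    def test_causal_mode_keeps_group_delay(self):
        spec = FilterSpec(highpass_hz=None, lowpass_hz=40.0,
                          transition_bw_hz=20.0, causal=True)
        x = np.zeros(500)
        x[50] = 1.0
        y = windowed_sinc_filter(x, self.rate, spec)
        assert np.argmax(y) > 50   # impulse response delayed, not centred


class TestResample:
    def test_identity_when_rates_equal(self, rng):
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(resample(x, 250.0, 250.0), x)

    def test_constant_maps_to_constant(self):
        out = resample(np.full(5000, 3.0), 5000.0, 250.0)
        mid = out[50:-50]
        np.testing.assert_allclose(mid, 3.0, atol=1e-6)

    def test_tone_survives_decimation_at_correct_frequency(self):
        rate_in, rate_out = 5000.0, 250.0
        t = np.arange(int(4 * rate_in)) / rate_in
        x = np.sin(2 * np.pi * 10.0 * t)
        y = resample(x, rate_in, rate_out)
        f = np.fft.rfftfreq(len(y), 1 / rate_out)
        peak = f[np.argmax(np.abs(np.fft.rfft(y)))]
        assert peak == pytest.approx(10.0, abs=f[1])

    def test_upsampling_and_bad_rates_raise(self):
        with pytest.raises(ValueError):
            resample(np.zeros(10), 250.0, 500.0)
        with pytest.raises(ValueError):
            resample(np.zeros(10), 0.0, 250.0)


class TestEpoching:
    def _events(self, times):
        return pd.DataFrame({"type": "stim", "time_ms": times,
                             "trial": np.arange(len(times))})

    def test_constant_channel_zero_after_baseline(self):
        rate = 250.0
        data = np.full((2, 1000), 7.0)
        eeg = _eeg(data, rate, self._events([1000.0, 2000.0]))
        eps = epoch(eeg)
        np.testing.assert_allclose(eps.data, 0.0, atol=1e-12)

    def test_count_conservation_and_truncation(self, rng):
        rate = 250.0
        data = rng.standard_normal((1, 2500))
        eeg = _eeg(data, rate, self._events([100.0, 1000.0, 2000.0, 3000.0]))
        eps = epoch(eeg)           # first event truncated (window starts < 0)
        assert eps.n_trials == 3
        assert 0.0 in eps.time_axis
        assert eps.time_axis[0] == -200.0 and eps.time_axis[-1] == 500.0

    def test_epoch_content_matches_recording(self, rng):
        rate = 250.0
        data = rng.standard_normal((1, 1000))
        eeg = _eeg(data, rate, self._events([2000.0]))
        eps = epoch(eeg, baseline=None)
        i = int(2000.0 * rate / 1000.0)
        np.testing.assert_array_equal(eps.data[0, 0], data[0, i - 50:i + 126])


class TestRejectEpochs:
    def _epochs(self, data):
        from stncc import EpochSet
        n, c, t = data.shape
        return EpochSet(data=data, time_axis=(np.arange(t) - 10) * 4.0,
                        channel_labels=tuple(f"ch{i}" for i in range(c)),
                        trial_ids=np.arange(n))

    def test_single_outlier_removed(self, rng):
        data = rng.standard_normal((40, 2, 100))
        data[17] *= 100.0
        eps = self._epochs(data)
        out, log = reject_epochs(eps, 5.0)
        assert list(log["trial"]) == [17]
        assert out.n_trials == 39
        # direct z-score oracle
        peaks = np.abs(data).max(axis=(1, 2))
        z = (peaks - peaks.mean()) / peaks.std()
        assert (z > 5).sum() == 1 and np.argmax(z) == 17

    def test_identical_epochs_none_removed(self):
        data = np.ones((10, 2, 50))
        out, log = reject_epochs(self._epochs(data), 5.0)
        assert out.n_trials == 10 and len(log) == 0

    def test_infinite_threshold_is_identity(self, rng):
        data = rng.standard_normal((10, 2, 50))
        out, log = reject_epochs(self._epochs(data), np.inf)
        assert out.n_trials == 10

    def test_all_rejected_raises(self, rng):
        data = rng.standard_normal((10, 2, 50))
        with pytest.raises(ValueError, match="all epochs rejected"):
            reject_epochs(self._epochs(data), -10.0)


class TestSubtractTmsOnly:
    def test_identical_inputs_cancel(self, rng):
        a = rng.standard_normal((4, 100))
        assert not subtract_tms_only(a, a).any()

    def test_zero_tms_only_is_identity(self, rng):
        a = rng.standard_normal((4, 100))
        np.testing.assert_array_equal(subtract_tms_only(a, np.zeros_like(a)), a)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            subtract_tms_only(np.zeros((4, 100)), np.zeros((4, 99)))
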