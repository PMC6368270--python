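"""Continuous-EEG preprocessing: TMS mute-window interpolation, windowed-sinc
filtering, resampling, epoching, amplitude-based epoch rejection, and
TMS-evoked-potential subtraction.

The TMS pulse artifact is handled by excising a 15 ms "mute window"
starting three samples before the pulse and replacing it with a cubic
polynomial fitted by least squares to anchor samples flanking the window
(10 ms on each side by default).  Filtering uses one-pass Blackman
windowed-sinc FIR filters with half-amplitude (-6 dB) cutoff semantics;
by default the linear-phase group delay is compensated so event
latencies are preserved (set ``causal=True`` on the spec for a strictly
causal pass that retains the delay).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import scipy.signal

from .containers import ContinuousEEG, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec", "interpolate_mute_window", "design_windowed_sinc",
    "windowed_sinc_filter", "resample", "epoch", "reject_epochs",
    "subtract_tms_only", "preprocess_continuous",
]


@dataclass
class FilterSpec:
    """Band edges and design rules for the windowed-sinc filters.

    Cutoffs are half-amplitude (-6 dB) frequencies.  The transition
    bandwidth defaults to 25% of each cutoff with a floor of 0.05 Hz;
    the filter length follows the Blackman design rule
    ``N ≈ 5.5 / (transition bandwidth / rate)``.
    """

    highpass_hz: float | None = 0.05
    lowpass_hz: float | None = 40.0
    window: str = "blackman"
    transition_bw_hz: float | None = None
    causal: bool = False

    def validate(self, rate: float) -> None:
        hp = self.highpass_hz or 0.0
        lp = self.lowpass_hz if self.lowpass_hz is not None else rate / 2.0
        if self.highpass_hz is not None and self.highpass_hz <= 0:
            raise ValueError("highpass cutoff must be > 0")
        if not hp < lp:
            raise ValueError("need highpass < lowpass")
        for c in (self.highpass_hz, self.lowpass_hz):
            if c is not None and c >= rate / 2.0:
                raise ValueError(f"cutoff {c} Hz is at or above Nyquist ({rate / 2} Hz)")

    def transition_bw(self, cutoff_hz: float) -> float:
        if self.transition_bw_hz is not None:
            return self.transition_bw_hz
        return max(0.25 * cutoff_hz, 0.05)


def interpolate_mute_window(signal: np.ndarray, rate: float, pulse_time_ms: float,
                            window_ms: float = 15.0, pre_samples: int = 3,
                            anchor_ms: float = 10.0) -> np.ndarray:
    """Replace the TMS mute window with a least-squares cubic fit.

    The mute window spans ``window_ms`` starting ``pre_samples`` samples
    before the pulse.  A degree-3 polynomial is fitted to the anchor
    samples (``anchor_ms`` on each side of the window) and evaluated
    inside the window; all other samples are returned bit-identical.
    Works on a single channel (1-D) or channels x samples (2-D).
    """
    sig = np.array(signal, dtype=float)
    _interpolate_mute_inplace(sig, rate, pulse_time_ms, window_ms,
                              pre_samples, anchor_ms)
    return sig


def _interpolate_mute_inplace(sig: np.ndarray, rate: float, pulse_time_ms: float,
                              window_ms: float, pre_samples: int,
                              anchor_ms: float) -> None:
    n = sig.shape[-1]
    i_pulse = int(round(pulse_time_ms * rate / 1000.0))
    i0 = i_pulse - pre_samples
    n_mute = int(round(window_ms * rate / 1000.0))
    i1 = i0 + n_mute                      # exclusive
    n_anchor = int(round(anchor_ms * rate / 1000.0))
    a0, a1 = i0 - n_anchor, i1 + n_anchor
    if i0 < 0 or i1 > n or a0 < 0 or a1 > n:
        raise ValueError("mute window plus anchors must lie inside the signal span")
    anchor_idx = np.r_[a0:i0, i1:a1]
    if len(anchor_idx) < 4:
        raise ValueError("anchor span too short: need >= 4 samples for a cubic fit")
    # centre/scale the abscissa for conditioning
    t_all = np.arange(n, dtype=float)
    c = 0.5 * (i0 + i1 - 1)
    s = max(a1 - a0, 1)
    tx = (anchor_idx - c) / s
    V = np.vander(tx, 4)
    y = sig[..., anchor_idx]
    coef, *_ = np.linalg.lstsq(V, y.T if sig.ndim == 2 else y, rcond=None)
    tm = (t_all[i0:i1] - c) / s
    Vm = np.vander(tm, 4)
    fitted = Vm @ coef
    sig[..., i0:i1] = fitted.T if sig.ndim == 2 else fitted


def design_windowed_sinc(cutoff_hz: float, rate: float, btype: str,
                         spec: FilterSpec) -> np.ndarray:
    """FIR taps for one windowed-sinc filter (half-amplitude cutoff)."""
    if cutoff_hz >= rate / 2.0:
        raise ValueError(f"cutoff {cutoff_hz} Hz at or above Nyquist ({rate / 2} Hz)")
    tb = spec.transition_bw(cutoff_hz)
    numtaps = int(np.ceil(5.5 * rate / tb))
    if numtaps % 2 == 0:
        numtaps += 1
    return scipy.signal.firwin(numtaps, cutoff_hz, window=spec.window,
                               pass_zero=(btype == "low"), fs=rate)


def _apply_fir(x: np.ndarray, taps: np.ndarray, causal: bool) -> np.ndarray:
    n = x.shape[-1]
    full = scipy.signal.oaconvolve(x, taps[np.newaxis, :] if x.ndim == 2 else taps,
                                   axes=-1)
    if causal:
        return full[..., :n]
    delay = (len(taps) - 1) // 2
    return full[..., delay:delay + n]


def windowed_sinc_filter(signal: np.ndarray, rate: float,
                         spec: FilterSpec | None = None) -> np.ndarray:
    """Apply the high-pass and/or low-pass windowed-sinc FIR once each.

    Each filter is applied in a single pass (no forward-backward
    filtering, which would square the magnitude response and move the
    half-amplitude point).  Gain at each stated cutoff is 0.5.
    """
    if spec is None:
        spec = FilterSpec()
    spec.validate(rate)
    out = np.asarray(signal, dtype=float)
    if spec.highpass_hz is not None:
        taps = design_windowed_sinc(spec.highpass_hz, rate, "high", spec)
        out = _apply_fir(out, taps, spec.causal)
    if spec.lowpass_hz is not None:
        taps = design_windowed_sinc(spec.lowpass_hz, rate, "low", spec)
        out = _apply_fir(out, taps, spec.causal)
    return out


def resample(signal: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Anti-aliased polyphase resampling (last axis)."""
    if rate_in <= 0 or rate_out <= 0:
        raise ValueError("rates must be positive")
    if rate_out > rate_in:
        raise ValueError("rate_out must not exceed rate_in")
    if rate_out == rate_in:
        return np.asarray(signal, dtype=float).copy()
    frac = Fraction(rate_out / rate_in).limit_denominator(10000)
    return scipy.signal.resample_poly(np.asarray(signal, dtype=float),
                                      frac.numerator, frac.denominator, axis=-1)


def epoch(eeg: ContinuousEEG, event_type: str = "stim",
          tmin_ms: float = -200.0, tmax_ms: float = 500.0,
          baseline: tuple[float, float] | None = (-200.0, 0.0)) -> EpochSet:
    """Segment the recording around events and baseline-correct.

    One epoch per event of *event_type*; events whose window would be
    truncated by the record edges are dropped with a logged warning.
    Baseline correction subtracts, per channel and epoch, the mean over
    samples with ``baseline[0] <= t < baseline[1]`` (the stimulus-onset
    sample itself is excluded).
    """
    rate = eeg.rate
    k0 = int(round(tmin_ms * rate / 1000.0))
    k1 = int(round(tmax_ms * rate / 1000.0))
    time_axis = np.arange(k0, k1 + 1) * 1000.0 / rate
    ev = eeg.events[eeg.events["type"] == event_type]
    n = eeg.n_samples
    segs, ids, dropped = [], [], []
    for t, trial in zip(ev["time_ms"], ev["trial"]):
        i = int(round(t * rate / 1000.0))
        if i + k0 < 0 or i + k1 + 1 > n:
            dropped.append(trial)
            continue
        segs.append(eeg.data[:, i + k0:i + k1 + 1])
        ids.append(trial)
    if dropped:
        logger.warning("dropped %d truncated epoch(s): trials %s", len(dropped), dropped)
    data = np.array(segs, dtype=float)
    if data.size == 0:
        raise ValueError(f"no complete epochs for event type {event_type!r}")
    if baseline is not None:
        b0, b1 = baseline
        mask = (time_axis >= b0) & (time_axis < b1)
        if not mask.any():
            raise ValueError("baseline window contains no samples")
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)
    return EpochSet(data=data, time_axis=time_axis,
                    channel_labels=tuple(eeg.channel_labels),
                    trial_ids=np.asarray(ids),
                    baseline_window=baseline if baseline else (np.nan, np.nan))


def reject_epochs(epochs: EpochSet, sd_threshold: float = 5.0
                  ) -> tuple[EpochSet, pd.DataFrame]:
    """Remove epochs with improbably large peak amplitude.

    Each epoch's peak absolute amplitude (over all channels and samples)
    is compared against the distribution of peaks across epochs; epochs
    exceeding ``mean + sd_threshold * SD`` are removed.  Returns the
    surviving set and a removal log.
    """
    if epochs.n_trials < 2:
        raise ValueError("need at least 2 epochs to estimate the peak distribution")
    peaks = np.abs(epochs.data).max(axis=(1, 2))
    mu, sd = peaks.mean(), peaks.std()
    if np.isinf(sd_threshold) or sd == 0:
        keep = np.ones(len(peaks), dtype=bool)
    else:
        keep = peaks <= mu + sd_threshold * sd
    if not keep.any():
        raise ValueError(
            "all epochs rejected; review sd_threshold or the peak distribution")
    log = pd.DataFrame({
        "trial": epochs.trial_ids[~keep],
        "peak_uv": peaks[~keep],
        "z": (peaks[~keep] - mu) / sd if sd > 0 else np.nan,
    })
    out = EpochSet(epochs.data[keep], epochs.time_axis, epochs.channel_labels,
                   epochs.trial_ids[keep], epochs.baseline_window)
    return out, log


def subtract_tms_only(erp_condition: np.ndarray, erp_tms_only: np.ndarray
                      ) -> np.ndarray:
    """Remove the TMS-evoked potential from a condition-average ERP.

    Element-wise difference of two channels x time trace sets sharing
    the same channel order and time axis.
    """
    a = np.asarray(erp_condition, dtype=float)
    b = np.asarray(erp_tms_only, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"trace-set shapes differ: {a.shape} vs {b.shape}")
    return a - b


def preprocess_continuous(eeg: ContinuousEEG, target_rate: float = 250.0,
                          spec: FilterSpec | None = None,
                          mute_window_ms: float = 15.0, mute_pre_samples: int = 3,
                          mute_anchor_ms: float = 10.0) -> ContinuousEEG:
    """Mute-window interpolation at the raw rate, then resample and filter.

    Mirrors the acquisition chain: the pulse artifact is excised and
    interpolated before any resampling or filtering so it cannot smear.
    """
    data = np.array(eeg.data, dtype=float)
    tms_times = eeg.events.loc[eeg.events["type"] == "tms", "time_ms"]
    for t in tms_times:
        _interpolate_mute_inplace(data, eeg.rate, t, mute_window_ms,
                                  mute_pre_samples, mute_anchor_ms)
    data = resample(data, eeg.rate, target_rate)
    data = windowed_sinc_filter(data, target_rate, spec)
    return ContinuousEEG(data=data, rate=target_rate,
                         channel_labels=tuple(eeg.channel_labels),
                         events=eeg.events.copy())
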