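"""Synthetic TMS-EEG session generator.

Produces ground-truth-known sessions with the statistical structure the
analysis chain assumes: four interleaved conditions (visual target only,
TMS ipsilateral / contralateral to the target, TMS only), Gaussian-bump
evoked components (P45, posterior and frontal VAN, LP) with per-trial
amplitude and latency jitter, a large brief biphasic TMS pulse artifact,
1/f background noise, and behavior (visibility ratings, go/no-go
responses, lognormal reaction times).

The model of the conscious correlates: VAN and LP amplitudes scale
linearly with the trial's visibility rating (rating/3), so unseen trials
(rating 0) carry exactly zero VAN/LP.  Contralateral TMS suppresses
visibility via the configured rating distribution, which is what makes
the ipsilateral-contralateral difference isolate the correlates.

Ground-truth onset latencies are analytic: a Gaussian bump of realized
amplitude ``A``, peak ``mu`` and width ``sigma`` crosses ``|thr|`` at
``mu - sigma*sqrt(2 ln(|A|/thr))`` and stays beyond it for twice that
half-duration; an onset exists iff the excursion exceeds the threshold
for at least the minimum duration (defaults: 1.5 µV, 20 ms).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import (
    COMPONENT_KINDS, CONDITIONS, TARGET_CONDITIONS, TMS_CONDITIONS,
    ComponentParams, SessionConfig, default_component_params,
)
from .containers import ContinuousEEG

__all__ = [
    "component_template", "inject_tms_artifact", "powerlaw_noise",
    "simulate_behavior", "simulate_session", "gaussian_onset",
]


def component_template(kind: str, params: ComponentParams | None = None,
                       time_axis: np.ndarray | None = None) -> np.ndarray:
    """Evaluate one component's waveform (µV) on *time_axis* (ms).

    The waveform is a Gaussian bump with the component's peak latency,
    peak amplitude and width (SD), truncated to zero beyond ±3 widths.
    """
    if kind not in COMPONENT_KINDS:
        raise ValueError(f"unknown component kind {kind!r}; valid kinds: {COMPONENT_KINDS}")
    if params is None:
        params = default_component_params()[kind]
    if time_axis is None:
        raise ValueError("time_axis is required")
    if params.width_ms <= 0:
        raise ValueError("width_ms must be > 0")
    t = np.asarray(time_axis, dtype=float)
    z = (t - params.peak_latency_ms) / params.width_ms
    wave = params.peak_amplitude_uv * np.exp(-0.5 * z * z)
    wave[np.abs(z) > 3.0] = 0.0
    return wave


def _gaussian_bump(t: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    z = (t - mu) / sigma
    w = amp * np.exp(-0.5 * z * z)
    w[np.abs(z) > 3.0] = 0.0
    return w


def gaussian_onset(amplitude_uv: float, peak_ms: float, width_ms: float,
                   threshold_uv: float = 1.5, min_duration_ms: float = 20.0
                   ) -> float | None:
    """Analytic threshold-duration onset of a Gaussian bump, or None."""
    a = abs(amplitude_uv)
    thr = abs(threshold_uv)
    if a <= thr:
        return None
    half = width_ms * math.sqrt(2.0 * math.log(a / thr))
    if 2.0 * half < min_duration_ms:
        return None
    return peak_ms - half


def inject_tms_artifact(signal: np.ndarray, rate: float, pulse_time_ms: float,
                        amplitude_uv: float = 2000.0,
                        duration_ms: float = 2.0) -> np.ndarray:
    """Add a biphasic pulse artifact (one sine cycle) starting at *pulse_time_ms*.

    The artifact is confined to ``duration_ms`` (<= 2 ms by default); the
    signal is unchanged elsewhere.  Returns a new array.
    """
    sig = np.array(signal, dtype=float)
    n = sig.shape[-1]
    if not (0 <= pulse_time_ms <= (n - 1) / rate * 1000.0):
        raise ValueError("pulse_time_ms lies outside the signal span")
    i0 = int(round(pulse_time_ms * rate / 1000.0))
    n_art = max(int(round(duration_ms * rate / 1000.0)), 1)
    i1 = min(i0 + n_art, n)
    # sample the one-cycle sine at bin midpoints so coarse rates do not
    # land exactly on its zero crossings
    tt = (np.arange(i1 - i0) + 0.5) / rate * 1000.0
    sig[..., i0:i1] += amplitude_uv * np.sin(2.0 * np.pi * tt / duration_ms)
    return sig


def powerlaw_noise(n: int, exponent: float, sd: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ∝ f^(-exponent/2), RMS = *sd*."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    if exponent == 0:
        return sd * white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.empty_like(f)
    scale[0] = 0.0                      # no DC component
    scale[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n)
    rms = x.std()
    return x * (sd / rms) if rms > 0 else x


def _draw_conditions(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    conds = np.concatenate([
        np.repeat(c, cfg.n_trials_per_condition.get(c, 0)) for c in CONDITIONS
    ])
    rng.shuffle(conds)
    return conds


def simulate_behavior(cfg: SessionConfig, rng: np.random.Generator | None = None
                      ) -> pd.DataFrame:
    """Draw the behavioral trial table (no EEG).

    Columns: trial, condition, target_side, tms_side, stim_onset_ms,
    tms_time_ms, go, rating, rt_ms.  Stimulus onsets fall on the target
    sampling grid so that epochs align exactly.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    conds = _draw_conditions(cfg, rng)
    n = len(conds)
    bp = cfg.behavior_params
    grid_ms = 1000.0 / cfg.target_rate

    lo, hi = cfg.iti_range_ms
    itis = rng.uniform(lo, hi, size=n)
    itis = np.round(itis / grid_ms) * grid_ms
    pad = math.ceil(cfg.pad_s * 1000.0 / grid_ms) * grid_ms
    onsets = pad + np.cumsum(itis) - itis[0]

    rows = []
    for i, cond in enumerate(conds):
        target_side = rng.choice(["L", "R"]) if cond in TARGET_CONDITIONS else ""
        if cond == "ipsi":
            tms_side = target_side
        elif cond == "contra":
            tms_side = {"L": "R", "R": "L"}[target_side]
        elif cond == "tms_only":
            tms_side = rng.choice(["L", "R"])
        else:
            tms_side = ""
        rating = int(rng.choice(4, p=bp.p_rating[cond]))
        go = bool(rng.random() < bp.p_go_given_rating[rating])
        if go:
            rt = float(rng.lognormal(math.log(bp.rt_median_ms[rating]), bp.rt_log_sd))
        else:
            rt = np.nan
        rows.append({
            "trial": i,
            "condition": cond,
            "target_side": target_side,
            "tms_side": tms_side,
            "stim_onset_ms": onsets[i],
            "tms_time_ms": onsets[i] + cfg.tms_delay_ms if cond in TMS_CONDITIONS else np.nan,
            "go": go,
            "rating": rating,
            "rt_ms": rt,
        })
    return pd.DataFrame(rows)


def simulate_session(cfg: SessionConfig
                     ) -> tuple[ContinuousEEG, pd.DataFrame, pd.DataFrame]:
    """Simulate one full session.

    Returns ``(eeg, trial_table, ground_truth)``.  Deterministic given
    ``cfg.seed``.  The ground-truth table records, per trial, realized
    component amplitudes at the unit-weight channel and analytic VAN/LP
    onset latencies of the noiseless conscious-correlate waveform
    (NaN when the threshold-duration criterion is not met).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    table = simulate_behavior(cfg, rng)
    n_trials = len(table)
    channels = tuple(cfg.channels)
    n_ch = len(channels)
    rate = cfg.raw_rate
    grid_ms = 1000.0 / rate

    last = table["stim_onset_ms"].max() if n_trials else 0.0
    total_ms = last + cfg.epoch_span_ms[1] + cfg.pad_s * 1000.0
    n_samp = int(round(total_ms / grid_ms)) + 1

    data = np.zeros((n_ch, n_samp), dtype=np.float32)
    nm = cfg.noise_model
    for ci in range(n_ch):
        data[ci] = powerlaw_noise(n_samp, nm.exponent, nm.sd_uv, rng).astype(np.float32)

    # Per-channel weight vectors per component.
    weight_vecs = {}
    for kind, comp in cfg.component_params.items():
        w = np.zeros(n_ch)
        for ch, g in comp.scalp_weights.items():
            w[channels.index(ch)] = g
        weight_vecs[kind] = w

    gt_rows = []
    events = []
    for row in table.itertuples(index=False):
        onset = row.stim_onset_ms
        i_on = int(round(onset / grid_ms))
        events.append(("stim", onset, row.trial))
        has_target = row.condition in TARGET_CONDITIONS
        has_tms = row.condition in TMS_CONDITIONS
        realized = {}
        for kind, comp in cfg.component_params.items():
            is_visual = kind != "P45"
            if is_visual and not has_target:
                continue
            if kind == "P45" and not has_tms:
                continue
            scale = (row.rating / 3.0) if comp.rating_scaled else 1.0
            if scale == 0.0:
                realized[kind] = (0.0, comp.peak_latency_ms)
                continue
            amp = scale * (comp.peak_amplitude_uv
                           + rng.normal(0.0, comp.amplitude_sd_uv))
            mu = comp.peak_latency_ms + rng.normal(0.0, comp.latency_jitter_sd_ms)
            realized[kind] = (amp, mu)
            # add to the recording over the bump's ±3-width support
            t0 = mu - 3.0 * comp.width_ms
            t1 = mu + 3.0 * comp.width_ms
            j0 = max(i_on + int(math.floor(t0 / grid_ms)), 0)
            j1 = min(i_on + int(math.ceil(t1 / grid_ms)) + 1, n_samp)
            if j1 <= j0:
                continue
            t_local = (np.arange(j0, j1) - i_on) * grid_ms
            bump = _gaussian_bump(t_local, amp, mu, comp.width_ms)
            data[:, j0:j1] += np.outer(weight_vecs[kind], bump).astype(np.float32)

        if has_tms:
            t_pulse = onset + cfg.tms_delay_ms
            events.append(("tms", t_pulse, row.trial))
            i_p = int(round(t_pulse / grid_ms))
            n_art = max(int(round(cfg.tms_artifact_duration_ms * rate / 1000.0)), 1)
            tt = (np.arange(n_art) + 0.5) * grid_ms
            art = cfg.tms_artifact_amplitude_uv * np.sin(
                2.0 * np.pi * tt / cfg.tms_artifact_duration_ms)
            j1 = min(i_p + n_art, n_samp)
            data[:, i_p:j1] += art[: j1 - i_p].astype(np.float32)
        if row.go and np.isfinite(row.rt_ms):
            events.append(("response", onset + row.rt_ms, row.trial))

        van_amp, van_mu = realized.get("VAN_posterior", (0.0, np.nan))
        lp_amp, lp_mu = realized.get("LP", (0.0, np.nan))
        p45_amp = realized.get("P45", (0.0, np.nan))[0]
        van_w = cfg.component_params.get("VAN_posterior")
        lp_w = cfg.component_params.get("LP")
        van_on = (gaussian_onset(van_amp, van_mu, van_w.width_ms)
                  if van_w is not None and van_amp != 0.0 else None)
        lp_on = (gaussian_onset(lp_amp, lp_mu, lp_w.width_ms)
                 if lp_w is not None and lp_amp != 0.0 else None)
        gt_rows.append({
            "trial": row.trial,
            "condition": row.condition,
            "rating": row.rating,
            "rt_ms": row.rt_ms,
            "van_amplitude_uv": van_amp,
            "lp_amplitude_uv": lp_amp,
            "p45_amplitude_uv": p45_amp,
            "true_van_onset_ms": np.nan if van_on is None else van_on,
            "true_lp_onset_ms": np.nan if lp_on is None else lp_on,
        })

    ev = pd.DataFrame(events, columns=["type", "time_ms", "trial"])
    eeg = ContinuousEEG(data=data, rate=rate, channel_labels=channels, events=ev)
    return eeg, table, pd.DataFrame(gt_rows)
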