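"""End-to-end orchestration: simulate -> preprocess -> ERP -> single-trial
difference -> denoise -> onsets -> permutation and behavioral statistics.

``run_pipeline`` executes the whole chain from a configuration, writes
every stage's outputs (float32 + JSON sidecars for arrays, TSV for
tables) plus a machine-readable report and a run manifest with file
digests and per-stage trial accounting, and returns ``(manifest,
report)``.  Every number in the report is computed by a stage and also
present in that stage's output file.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import AnalysisConfig, SessionConfig
from .containers import EpochSet
from .denoise import apply_denoiser, fit_denoiser
from .erp import LP_WINDOW, VAN_FRONTAL, VAN_POSTERIOR, average_erp, window_mean
from .io import save_continuous, save_epochs, save_table, sha256_of
from .onsets import OnsetCriteria, estimate_onsets, onset_rt_comparison
from .preprocess import FilterSpec, epoch, preprocess_continuous, reject_epochs, \
    subtract_tms_only
from .single_trial import matched_difference, moving_average_rows, sort_by_rt
from .stats import behavioral_probabilities, rt_summaries, \
    sign_flip_permutation_test, significant_spans
from .synth import simulate_session

__all__ = ["run_pipeline", "load_pipeline_config", "analyze_epochs",
           "session_difference_image", "pooled_onset_analysis"]


def load_pipeline_config(path: str | Path) -> tuple[SessionConfig, AnalysisConfig]:
    """Read a YAML file with optional ``session:`` and ``analysis:`` blocks."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    session = SessionConfig.from_dict(raw.get("session", {}))
    analysis = AnalysisConfig.from_dict(raw.get("analysis", {}))
    return session, analysis


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def analyze_epochs(epochs: EpochSet, table: pd.DataFrame,
                   analysis: AnalysisConfig, seed: int) -> dict:
    """Run the post-preprocessing analysis stages on clean epochs.

    Returns a dict with the condition-average ERPs, per-channel
    difference images (raw and denoised), onset estimates, permutation
    results and behavioral summaries.
    """
    surviving = set(epochs.trial_ids.tolist())
    tbl = table[table["trial"].isin(surviving)].reset_index(drop=True)
    cond_of = dict(zip(tbl["trial"], tbl["condition"]))
    cond_ids = {c: np.array([t for t in epochs.trial_ids if cond_of.get(t) == c])
                for c in ("vis_only", "ipsi", "contra", "tms_only")}

    # condition-average ERPs; TMS-evoked potential removed from TMS conditions
    erps = {c: average_erp(epochs, ids) for c, ids in cond_ids.items() if len(ids)}
    visual_erps = {}
    if "tms_only" in erps:
        for c in ("ipsi", "contra"):
            if c in erps:
                visual_erps[c] = subtract_tms_only(erps[c], erps["tms_only"])
    nc_difference = None
    if "ipsi" in erps and "contra" in erps:
        nc_difference = erps["ipsi"] - erps["contra"]

    # per-electrode window means of the grand-average difference (Fig. 4 analogue)
    window_rows = []
    if nc_difference is not None:
        for w in (VAN_POSTERIOR, VAN_FRONTAL, LP_WINDOW):
            means = window_mean(nc_difference, epochs.time_axis, w)
            for ch, m in zip(epochs.channel_labels, np.atleast_1d(means)):
                window_rows.append({"window": w.label, "electrode": ch,
                                    "mean_uv": float(m)})
    window_table = pd.DataFrame(window_rows)

    rt_of = dict(zip(tbl["trial"], tbl["rt_ms"]))
    criteria = OnsetCriteria(
        van_threshold_uv=analysis.van_threshold_uv,
        lp_threshold_uv=analysis.lp_threshold_uv,
        min_duration_ms=analysis.min_duration_ms)

    images, denoised_images, perms = {}, {}, {}
    onset_df, onset_summary = None, None
    for ch in analysis.channels_of_interest:
        ipsi = epochs.select_trials(cond_ids["ipsi"]).get_channel(ch)
        contra = epochs.select_trials(cond_ids["contra"]).get_channel(ch)
        ipsi_ids = epochs.select_trials(cond_ids["ipsi"]).trial_ids
        contra_ids = epochs.select_trials(cond_ids["contra"]).trial_ids
        rts = np.array([rt_of.get(t, np.nan) for t in ipsi_ids], dtype=float)
        raw_img = matched_difference(ipsi, contra, epochs.time_axis, seed=seed,
                                     channel=ch, ipsi_rts=rts,
                                     ipsi_trial_ids=ipsi_ids,
                                     contra_trial_ids=contra_ids)
        img = moving_average_rows(raw_img, analysis.moving_avg_width)
        images[ch] = img

        avg = img.data.mean(axis=0)
        n_baseline = int((epochs.time_axis < 0).sum())
        # sigma calibrated on the rows themselves; the moving average
        # leaves ~n/width independent rows behind the average
        den = fit_denoiser(avg, n_scales=analysis.n_scales,
                           threshold_k=analysis.denoise_k,
                           wavelet=analysis.wavelet, n_baseline=n_baseline,
                           noise_rows=img.data,
                           n_effective=img.n_rows / analysis.moving_avg_width,
                           provenance={"channel": ch, "n_trials": img.n_rows})
        dimg = img.replace(data=apply_denoiser(den, img.data))
        denoised_images[ch] = (den, sort_by_rt(dimg))

        # the permutation test needs exchangeable rows: use the raw
        # (un-smoothed) single-trial differences
        perms[ch] = sign_flip_permutation_test(
            raw_img.data, alpha=analysis.perm_alpha, n_perm=analysis.perm_n,
            seed=seed + 1, time_axis=epochs.time_axis, channel=ch)

        if ch == analysis.onset_channel:
            onset_df = estimate_onsets(denoised_images[ch][1], criteria)
            onset_summary = onset_rt_comparison(
                onset_df, exclude_pre_tms=analysis.exclude_pre_tms)

    behavior = behavioral_probabilities(tbl)
    rts_tbl = rt_summaries(tbl)
    return {
        "trial_table": tbl, "cond_ids": cond_ids, "erps": erps,
        "visual_erps": visual_erps, "nc_difference": nc_difference,
        "window_table": window_table, "images": images,
        "denoised_images": denoised_images, "permutations": perms,
        "onsets": onset_df, "onset_summary": onset_summary,
        "behavior": behavior, "rt_summaries": rts_tbl,
        "time_axis": epochs.time_axis,
    }


def session_difference_image(session: SessionConfig,
                             analysis: AnalysisConfig | None = None,
                             channel: str | None = None):
    """Simulate one session and return its smoothed difference image.

    Runs simulate -> mute-window interpolation -> resample -> filter ->
    epoch -> reject -> matched ipsilateral-contralateral difference ->
    across-trial moving average for a single channel.  Returns
    ``(image, time_axis)``.
    """
    analysis = analysis or AnalysisConfig()
    channel = channel or analysis.onset_channel
    eeg, table, _ = simulate_session(session)
    spec = FilterSpec(highpass_hz=analysis.highpass_hz,
                      lowpass_hz=analysis.lowpass_hz)
    clean = preprocess_continuous(
        eeg, target_rate=session.target_rate, spec=spec,
        mute_window_ms=analysis.mute_window_ms,
        mute_pre_samples=analysis.mute_pre_samples,
        mute_anchor_ms=analysis.mute_anchor_ms)
    epochs = epoch(clean, "stim", session.epoch_span_ms[0],
                   session.epoch_span_ms[1], analysis.baseline_ms)
    epochs, _ = reject_epochs(epochs, analysis.reject_sd)
    cond = dict(zip(table["trial"], table["condition"]))
    rt = dict(zip(table["trial"], table["rt_ms"]))
    ipsi = epochs.select_trials(
        np.array([t for t in epochs.trial_ids if cond[t] == "ipsi"]))
    contra = epochs.select_trials(
        np.array([t for t in epochs.trial_ids if cond[t] == "contra"]))
    rts = np.array([rt[t] for t in ipsi.trial_ids], dtype=float)
    img = matched_difference(ipsi.get_channel(channel),
                             contra.get_channel(channel), epochs.time_axis,
                             seed=session.seed, channel=channel, ipsi_rts=rts,
                             ipsi_trial_ids=ipsi.trial_ids,
                             contra_trial_ids=contra.trial_ids)
    img = moving_average_rows(img, analysis.moving_avg_width)
    return img, epochs.time_axis


def pooled_onset_analysis(sessions: list[SessionConfig],
                          analysis: AnalysisConfig | None = None,
                          channel: str | None = None) -> dict:
    """Pooled single-trial onset analysis across several sessions.

    Mirrors the grand single-trial analysis in which several
    participants' difference trials are stacked into one image: each
    session's smoothed difference image is computed, the rows are
    concatenated, one denoiser is fitted on the pooled average, and
    VAN/LP onsets are estimated per row.  Returns the onset summary
    (medians, LP-after-RT fraction, per-trial table).
    """
    analysis = analysis or AnalysisConfig()
    rows, rts = [], []
    time_axis = None
    for sess in sessions:
        img, time_axis = session_difference_image(sess, analysis, channel)
        rows.append(img.data)
        rts.append(img.rts)
    data = np.vstack(rows)
    rts = np.concatenate(rts)
    pooled = type(img)(data=data, time_axis=time_axis,
                       channel=img.channel, trial_ids=np.arange(len(data)),
                       rts=rts, order="p45",
                       smoothing={"moving_avg_width": analysis.moving_avg_width})
    n_baseline = int((time_axis < 0).sum())
    den = fit_denoiser(pooled.data.mean(axis=0), n_scales=analysis.n_scales,
                       threshold_k=analysis.denoise_k, wavelet=analysis.wavelet,
                       n_baseline=n_baseline, noise_rows=pooled.data,
                       n_effective=len(data) / analysis.moving_avg_width,
                       provenance={"channel": pooled.channel,
                                   "n_trials": len(data),
                                   "n_sessions": len(sessions)})
    denoised = pooled.replace(data=apply_denoiser(den, pooled.data))
    criteria = OnsetCriteria(
        van_threshold_uv=analysis.van_threshold_uv,
        lp_threshold_uv=analysis.lp_threshold_uv,
        min_duration_ms=analysis.min_duration_ms)
    est = estimate_onsets(denoised, criteria)
    summary = onset_rt_comparison(est, exclude_pre_tms=analysis.exclude_pre_tms)
    summary["denoiser"] = den
    summary["image"] = denoised
    return summary


def run_pipeline(session: SessionConfig, analysis: AnalysisConfig | None = None,
                 out_dir: str | Path | None = None,
                 keep_continuous: bool = False) -> tuple[dict, dict]:
    """Execute the full pipeline; returns ``(manifest, report)``.

    Deterministic given ``session.seed``.  With *out_dir* set, all stage
    outputs, ``report.json`` and ``manifest.json`` are written there.
    """
    analysis = analysis or AnalysisConfig()
    session.validate()
    analysis.validate()
    out = Path(out_dir) if out_dir is not None else None
    files: dict[str, Path] = {}
    counts: dict[str, int] = {}

    # 1. simulate
    eeg, table, truth = simulate_session(session)
    counts["trials_simulated"] = len(table)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        files["trials"] = save_table(table, out / "trials.tsv")
        files["ground_truth"] = save_table(truth, out / "ground_truth.tsv")
        if keep_continuous:
            files.update({f"continuous_{k}": v for k, v in
                          save_continuous(eeg, out).items()})

    # 2. preprocess: mute-window interpolation, resample, filter, epoch, reject
    spec = FilterSpec(highpass_hz=analysis.highpass_hz,
                      lowpass_hz=analysis.lowpass_hz)
    clean = preprocess_continuous(
        eeg, target_rate=session.target_rate, spec=spec,
        mute_window_ms=analysis.mute_window_ms,
        mute_pre_samples=analysis.mute_pre_samples,
        mute_anchor_ms=analysis.mute_anchor_ms)
    del eeg
    epochs = epoch(clean, "stim", session.epoch_span_ms[0],
                   session.epoch_span_ms[1], analysis.baseline_ms)
    del clean
    counts["epochs_extracted"] = epochs.n_trials
    epochs, removal_log = reject_epochs(epochs, analysis.reject_sd)
    counts["epochs_rejected"] = len(removal_log)
    counts["epochs_analyzed"] = epochs.n_trials
    if out is not None:
        files["removal_log"] = save_table(removal_log, out / "removal_log.tsv")
        files.update({f"epochs_{k}": v for k, v in save_epochs(epochs, out).items()})

    # 3-7. analysis stages
    res = analyze_epochs(epochs, table, analysis, seed=session.seed)

    report = {
        "version": __version__,
        "seed": session.seed,
        "counts": counts,
        "median_van_onset_ms": None,
        "median_lp_onset_ms": None,
        "fraction_lp_after_rt": None,
        "behavior": {
            "accuracy": res["behavior"]["accuracy"],
        },
        "rt": {},
        "permutation_significant_spans_ms": {
            ch: significant_spans(p) for ch, p in res["permutations"].items()},
    }
    if res["onset_summary"] is not None:
        s = res["onset_summary"]

        def _num(v):
            return float(v) if v is not None and np.isfinite(v) else None

        report["median_van_onset_ms"] = _num(s["median_van_onset_ms"])
        report["median_lp_onset_ms"] = _num(s["median_lp_onset_ms"])
        report["fraction_lp_after_rt"] = _num(s["fraction_lp_after_rt"])
        report["n_van_onsets"] = s["n_van"]
        report["n_lp_onsets"] = s["n_lp"]
    rts = res["rt_summaries"]
    for cond in ("vis_only", "ipsi", "contra"):
        row = rts[(rts["condition"] == cond) & (rts["rating"] == "all")]
        if len(row):
            report["rt"][cond] = {
                "median_ms": float(row["median_rt_ms"].iloc[0]),
                "sd_ms": float(row["sd_rt_ms"].iloc[0]),
                "n": int(row["n"].iloc[0]),
            }
    # ordering check of the headline structure: VAN onset precedes the
    # motor-corrected median RT, which precedes the LP onset
    ipsi_med = report["rt"].get("ipsi", {}).get("median_ms")
    if ipsi_med is not None and report["median_van_onset_ms"] is not None \
            and report["median_lp_onset_ms"] is not None:
        report["ordering_van_rt_lp"] = bool(
            report["median_van_onset_ms"] < ipsi_med - analysis.rt_motor_ms
            < report["median_lp_onset_ms"])

    if out is not None:
        # figure-equivalent tables
        t = res["time_axis"]
        if res["nc_difference"] is not None:
            df = pd.DataFrame(res["nc_difference"].T, columns=epochs.channel_labels)
            df.insert(0, "time_ms", t)
            files["difference_erp"] = save_table(df, out / "difference_erp.tsv")
        if len(res["window_table"]):
            files["window_means"] = save_table(res["window_table"],
                                               out / "window_means.tsv")
        for ch, p in res["permutations"].items():
            files[f"perm_{ch}"] = save_table(p.to_frame(), out / f"perm_{ch}.tsv")
        for ch, (den, dimg) in res["denoised_images"].items():
            den.to_json(out / f"denoiser_{ch}.json")
            files[f"denoiser_{ch}"] = out / f"denoiser_{ch}.json"
            rows = pd.DataFrame(dimg.data, columns=[f"t{int(v)}" for v in t])
            rows.insert(0, "rt_ms", dimg.rts)
            rows.insert(0, "trial_id", dimg.trial_ids)
            files[f"image_{ch}"] = save_table(rows, out / f"diff_image_{ch}.tsv")
        if res["onsets"] is not None:
            files["onsets"] = save_table(res["onsets"], out / "onsets.tsv")
        files["rt_summaries"] = save_table(res["rt_summaries"],
                                           out / "rt_summaries.tsv")
        (out / "report.json").write_text(json.dumps(_jsonable(report), indent=1))
        files["report"] = out / "report.json"

    manifest = {
        "version": __version__,
        "session_config": session.to_dict(),
        "analysis_config": asdict(analysis),
        "seed": session.seed,
        "counts": counts,
        "files": {k: {"path": str(v), "sha256": sha256_of(v)}
                  for k, v in files.items() if v is not None},
    }
    if out is not None:
        (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=1))
    return manifest, report
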