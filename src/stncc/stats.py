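"""Sign-flip permutation testing and behavioral summaries.

The single-trial difference waves enter the permutation test as paired
ipsilateral-minus-contralateral differences, so exchanging the condition
labels within a pair is equivalent to flipping the sign of the pair's
difference.  The null distribution of the mean difference is built from
random sign flips, and the two-tailed p-value uses the +1 finite-sample
correction (p >= 1/(n_perm+1), never exactly zero) — required for
validity at the strict alpha of 0.001.  No correction across timepoints
is applied; the strict alpha plays that role.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .config import TARGET_CONDITIONS

__all__ = [
    "PermutationResult", "sign_flip_permutation_test",
    "behavioral_probabilities", "rt_summaries", "significant_spans",
]

RATINGS = (0, 1, 2, 3)


@dataclass
class PermutationResult:
    """Per-timepoint outcome of the sign-flip permutation test."""

    time_axis: np.ndarray
    mean_diff: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    alpha: float
    n_permutations: int
    n_trials: int
    channel: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.time_axis, "mean_diff_uv": self.mean_diff,
            "p": self.p, "significant": self.significant,
        })


def sign_flip_permutation_test(differences: np.ndarray, alpha: float = 0.001,
                               n_perm: int = 10000, seed: int = 0,
                               time_axis: np.ndarray | None = None,
                               channel: str = "") -> PermutationResult:
    """Two-tailed sign-flip permutation test per timepoint.

    *differences* is trials x time for one channel.  Requires enough
    trials and permutations for the p-value floor 1/(n_perm+1) to reach
    *alpha* (with n trials the achievable two-tailed floor is 2^-(n-1),
    so at alpha = 0.001 at least 8 trials are needed).
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim == 1:
        d = d[:, np.newaxis]
    n, t = d.shape
    if 2.0 ** (-(n - 1)) > alpha:
        raise ValueError(
            f"{n} trials cannot reach alpha={alpha}: the two-tailed sign-flip "
            f"p-value floor is 2^-(n-1); need >= {int(np.ceil(1 + np.log2(1 / alpha)))}")
    min_perm = int(np.ceil(1.0 / alpha)) - 1
    if n_perm < min_perm:
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha}; "
                         f"need >= {min_perm} so that 1/(n_perm+1) <= alpha")
    rng = np.random.default_rng(seed)
    obs = d.mean(axis=0)
    signs = rng.integers(0, 2, size=(n_perm, n), dtype=np.int8) * 2 - 1
    null = (signs.astype(np.float64) @ d) / n
    exceed = (np.abs(null) >= np.abs(obs)[np.newaxis, :]).sum(axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    if time_axis is None:
        time_axis = np.arange(t, dtype=float)
    return PermutationResult(
        time_axis=np.asarray(time_axis, dtype=float), mean_diff=obs, p=p,
        significant=p <= alpha, alpha=alpha, n_permutations=n_perm,
        n_trials=n, channel=channel)


def significant_spans(result: PermutationResult) -> list[tuple[float, float]]:
    """Contiguous time spans (ms) where the permutation test is significant."""
    sig = result.significant
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    ends = np.r_[idx[breaks], idx[-1]]
    t = result.time_axis
    return [(float(t[s]), float(t[e])) for s, e in zip(starts, ends)]


def _cond_frames(table: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {c: table[table["condition"] == c] for c in table["condition"].unique()}


def behavioral_probabilities(table: pd.DataFrame,
                             participant_col: str | None = None) -> dict:
    """Empirical response probabilities with explicit denominators.

    Returns per-condition p(go | rating) and p(rating | go) tables
    (NaN where the conditioning cell is empty — a probability is never
    reported as 0/0), per-condition accuracy (go on target-present
    trials, no-go on TMS-only trials), and — when a participant column
    with >= 3 participants is present — the Pearson correlation across
    participants between overall accuracy and mean visibility rating on
    target-present trials.
    """
    if len(table) == 0:
        raise ValueError("empty trial table")
    bad = set(table["rating"].unique()) - set(RATINGS)
    if bad:
        raise ValueError(f"ratings outside 0-3: {sorted(bad)}")

    p_go_given_rating = {}
    p_rating_given_go = {}
    accuracy = {}
    for cond, sub in _cond_frames(table).items():
        by_rating = {}
        for r in RATINGS:
            cell = sub[sub["rating"] == r]
            by_rating[r] = {
                "p_go": float(cell["go"].mean()) if len(cell) else np.nan,
                "n": int(len(cell)),
            }
        p_go_given_rating[cond] = pd.DataFrame(by_rating).T.rename_axis("rating")
        go_trials = sub[sub["go"]]
        rate_given_go = {}
        for r in RATINGS:
            rate_given_go[r] = {
                "p_rating": (float((go_trials["rating"] == r).mean())
                             if len(go_trials) else np.nan),
                "n_go": int(len(go_trials)),
            }
        p_rating_given_go[cond] = pd.DataFrame(rate_given_go).T.rename_axis("rating")
        if cond in TARGET_CONDITIONS:
            accuracy[cond] = float(sub["go"].mean()) if len(sub) else np.nan
        else:
            accuracy[cond] = float((~sub["go"]).mean()) if len(sub) else np.nan

    out = {
        "p_go_given_rating": p_go_given_rating,
        "p_rating_given_go": p_rating_given_go,
        "accuracy": accuracy,
        "accuracy_visibility_r": None,
    }
    if participant_col is not None and participant_col in table.columns:
        per = []
        for pid, sub in table.groupby(participant_col):
            correct = np.where(sub["condition"].isin(TARGET_CONDITIONS),
                               sub["go"], ~sub["go"])
            vis = sub.loc[sub["condition"].isin(TARGET_CONDITIONS), "rating"]
            per.append((float(np.mean(correct)), float(vis.mean())))
        if len(per) >= 3:
            acc, vis = np.array(per).T
            r, p = scipy.stats.pearsonr(acc, vis)
            out["accuracy_visibility_r"] = float(r)
            out["accuracy_visibility_p"] = float(p)
            out["n_participants"] = len(per)
    return out


def rt_summaries(table: pd.DataFrame) -> pd.DataFrame:
    """Median RT and dispersion per condition and per (condition, rating).

    Medians are on raw milliseconds; dispersion is reported on both the
    raw and the log scale (RT distributions are right-skewed, so formal
    RT statistics should use the log scale).  Cells without go-trials
    are reported absent (NaN), never as 0/0.
    """
    go = table[table["go"] & np.isfinite(table["rt_ms"])]
    rows = []

    def _cell(cond, rating, rts):
        rts = np.asarray(rts, dtype=float)
        n = len(rts)
        rows.append({
            "condition": cond, "rating": rating, "n": n,
            "median_rt_ms": float(np.median(rts)) if n else np.nan,
            "sd_rt_ms": float(np.std(rts, ddof=1)) if n > 1 else np.nan,
            "sd_log_rt": float(np.std(np.log(rts), ddof=1)) if n > 1 else np.nan,
        })

    for cond, sub in _cond_frames(go).items():
        _cell(cond, "all", sub["rt_ms"])
        for r in RATINGS:
            _cell(cond, r, sub.loc[sub["rating"] == r, "rt_ms"])
    return pd.DataFrame(rows)
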