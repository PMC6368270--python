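"""Condition averaging, windowed amplitude measures, and across-participant
mass-univariate statistics with Benjamini-Hochberg FDR control.

Component windows follow the established visual-consciousness ERP
literature: a 12 ms window around the posterior VAN peak (166 ms) and
the frontal VAN peak (216 ms), and the 300-400 ms span for the late
positivity.  A sample belongs to a window when its centre time lies in
the closed interval — explicit so counts are deterministic on a 4 ms
sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .containers import EpochSet

__all__ = [
    "WindowSpec", "VAN_POSTERIOR", "VAN_FRONTAL", "LP_WINDOW",
    "average_erp", "window_mean", "bh_fdr", "mass_univariate_test",
]


@dataclass(frozen=True)
class WindowSpec:
    """A measurement window: centre ± width/2, or an explicit span."""

    label: str
    center_ms: float | None = None
    width_ms: float | None = None
    span_ms: tuple[float, float] | None = None

    def bounds(self) -> tuple[float, float]:
        if self.span_ms is not None:
            lo, hi = self.span_ms
        elif self.center_ms is not None and self.width_ms is not None:
            if self.width_ms <= 0:
                raise ValueError("width_ms must be > 0")
            lo = self.center_ms - self.width_ms / 2.0
            hi = self.center_ms + self.width_ms / 2.0
        else:
            raise ValueError("WindowSpec needs center+width or an explicit span")
        if not lo < hi:
            raise ValueError("window bounds must satisfy lo < hi")
        return lo, hi


VAN_POSTERIOR = WindowSpec("VAN_posterior", center_ms=166.0, width_ms=12.0)
VAN_FRONTAL = WindowSpec("VAN_frontal", center_ms=216.0, width_ms=12.0)
LP_WINDOW = WindowSpec("LP", span_ms=(300.0, 400.0))


def average_erp(epochs: EpochSet, selector) -> np.ndarray:
    """Pointwise mean (channels x time) over the selected trials.

    *selector* is a boolean mask over epochs, an array of trial ids, or
    a callable mapping trial ids to booleans.
    """
    if callable(selector):
        mask = np.array([bool(selector(t)) for t in epochs.trial_ids])
    else:
        arr = np.asarray(selector)
        if arr.dtype == bool:
            if len(arr) != epochs.n_trials:
                raise ValueError("boolean selector length must match epoch count")
            mask = arr
        else:
            mask = np.isin(epochs.trial_ids, arr)
    if not mask.any():
        raise ValueError(f"selector {selector!r} matched no trials")
    return epochs.data[mask].mean(axis=0)


def window_mean(trace: np.ndarray, time_axis: np.ndarray,
                window: WindowSpec) -> np.ndarray | float:
    """Mean amplitude over samples whose centres fall inside the window.

    *trace* may be 1-D (time) or n-D with time last; the mean is over the
    last axis.
    """
    lo, hi = window.bounds()
    t = np.asarray(time_axis, dtype=float)
    mask = (t >= lo) & (t <= hi)
    if not mask.any():
        raise ValueError(
            f"window {window.label!r} [{lo}, {hi}] ms contains no samples")
    out = np.asarray(trace, dtype=float)[..., mask].mean(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level *q*.

    Rejects all hypotheses with rank i <= max{i : p(i) <= i*q/m} in the
    sorted p-value order; ties share the sorted-order decision.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = (np.arange(1, m + 1) / m) * q
    passing = np.flatnonzero(ranked <= crit)
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        k = passing[-1]
        flags[order[: k + 1]] = True
    return flags


def mass_univariate_test(window_means_a: np.ndarray, window_means_b: np.ndarray,
                         q: float = 0.05,
                         electrodes: tuple[str, ...] | None = None,
                         window: WindowSpec | None = None) -> pd.DataFrame:
    """Paired t-tests at every electrode with BH-FDR across electrodes.

    Inputs are participants x electrodes matrices of window-mean
    amplitudes (paired by row).  Returns a per-electrode table with the
    t statistic, two-tailed p, and the FDR significance flag.
    """
    a = np.asarray(window_means_a, dtype=float)
    b = np.asarray(window_means_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("inputs must be equal-shape participants x electrodes matrices")
    if a.shape[0] < 2:
        raise ValueError("need >= 2 participants for a paired t-test")
    res = scipy.stats.ttest_rel(a, b, axis=0)
    t, p = np.asarray(res.statistic), np.asarray(res.pvalue)
    # zero paired-difference variance degenerates the t statistic: a
    # constant nonzero difference is a sure effect, a constant zero is none
    bad = ~np.isfinite(t)
    md = (a - b).mean(axis=0)
    t[bad] = np.where(md[bad] == 0, 0.0, np.sign(md[bad]) * np.inf)
    p[bad] = np.where(md[bad] == 0, 1.0, 0.0)
    flags = bh_fdr(p, q)
    labels = list(electrodes) if electrodes is not None else [
        f"ch{i}" for i in range(a.shape[1])]
    return pd.DataFrame({
        "electrode": labels, "t": t, "p": p, "significant": flags,
        "n_participants": a.shape[0],
        "window": window.label if window is not None else "",
    })
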