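"""Matched single-trial ipsilateral-contralateral difference images.

The core idea: equate trial counts between the two TMS conditions, sort
each condition's trials by the amplitude of the prominent TMS-evoked
potential P45 (so trials with comparable TMS-evoked responses are
paired), and subtract rank-by-rank.  The resulting rows are single-trial
estimates of the consciousness-related difference wave, which can then
be smoothed across trials, denoised and sorted by reaction time.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import DifferenceImage, ERPImage
from .erp import WindowSpec, window_mean

logger = logging.getLogger(__name__)

__all__ = [
    "equate_counts", "p45_amplitude", "matched_difference",
    "moving_average_rows", "gaussian_smooth_rows", "sort_by_rt",
]

#: Measurement window for the P45 TMS-evoked potential: 12 ms around its
#: peak at 135 ms after visual onset (45 ms after the TMS pulse).
P45_WINDOW = WindowSpec("P45", center_ms=135.0, width_ms=12.0)


def equate_counts(trials_a: np.ndarray, trials_b: np.ndarray, seed: int
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Randomly drop trials from the larger set until counts match.

    Returns ``(a, b, kept_a, kept_b)`` where the kept-index arrays are
    sorted so surviving trials keep their original order.
    """
    a = np.asarray(trials_a)
    b = np.asarray(trials_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both trial sets must be nonempty")
    rng = np.random.default_rng(seed)
    n = min(len(a), len(b))
    kept_a = np.sort(rng.choice(len(a), size=n, replace=False)) if len(a) > n \
        else np.arange(len(a))
    kept_b = np.sort(rng.choice(len(b), size=n, replace=False)) if len(b) > n \
        else np.arange(len(b))
    return a[kept_a], b[kept_b], kept_a, kept_b


def p45_amplitude(trial: np.ndarray, time_axis: np.ndarray,
                  window: WindowSpec = P45_WINDOW) -> np.ndarray | float:
    """Mean amplitude in the P45 window (per trial if 2-D input)."""
    return window_mean(trial, time_axis, window)


def matched_difference(ipsi: np.ndarray, contra: np.ndarray,
                       time_axis: np.ndarray, seed: int,
                       channel: str = "",
                       ipsi_rts: np.ndarray | None = None,
                       ipsi_trial_ids: np.ndarray | None = None,
                       contra_trial_ids: np.ndarray | None = None,
                       p45_window: WindowSpec = P45_WINDOW) -> DifferenceImage:
    """Build the P45-matched single-trial difference image.

    Counts are equated (random removal from the larger set), both sets
    are sorted ascending by P45 amplitude, and the rank-i contralateral
    trial is subtracted from the rank-i ipsilateral trial.  Row RTs come
    from the ipsilateral member of each pair.
    """
    ipsi = np.asarray(ipsi, dtype=float)
    contra = np.asarray(contra, dtype=float)
    if ipsi.ndim != 2 or contra.ndim != 2:
        raise ValueError("inputs must be trials x time matrices")
    if ipsi.shape[1] != len(time_axis) or contra.shape[1] != len(time_axis):
        raise ValueError("time axis length mismatch")
    n_i, n_c = ipsi.shape[0], contra.shape[0]
    if ipsi_rts is None:
        ipsi_rts = np.full(n_i, np.nan)
    if ipsi_trial_ids is None:
        ipsi_trial_ids = np.arange(n_i)
    if contra_trial_ids is None:
        contra_trial_ids = np.arange(n_c)

    ipsi_eq, contra_eq, kept_i, kept_c = equate_counts(ipsi, contra, seed)
    rts = np.asarray(ipsi_rts, dtype=float)[kept_i]
    ids_i = np.asarray(ipsi_trial_ids)[kept_i]
    ids_c = np.asarray(contra_trial_ids)[kept_c]

    amp_i = np.atleast_1d(p45_amplitude(ipsi_eq, time_axis, p45_window))
    amp_c = np.atleast_1d(p45_amplitude(contra_eq, time_axis, p45_window))
    order_i = np.argsort(amp_i, kind="stable")
    order_c = np.argsort(amp_c, kind="stable")

    diff = ipsi_eq[order_i] - contra_eq[order_c]
    return DifferenceImage(
        data=diff, time_axis=np.asarray(time_axis, dtype=float), channel=channel,
        trial_ids=ids_i[order_i], rts=rts[order_i], order="p45",
        order_key=amp_i[order_i],
        contra_trial_ids=ids_c[order_c],
        p45_ipsi=amp_i[order_i], p45_contra=amp_c[order_c],
    )


def _truncated_mean_rows(data: np.ndarray, half: int) -> np.ndarray:
    n = data.shape[0]
    out = np.empty_like(data, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = data[lo:hi].mean(axis=0)
    return out


def moving_average_rows(image: ERPImage, width: int = 5,
                        smooth_rts: bool = True) -> ERPImage:
    """Across-trial moving average of the image rows.

    Each output row is the mean of the ``width`` nearest rows, with the
    window truncated (and renormalised) at the edges.  With
    ``smooth_rts`` the row RTs receive the same moving average (ignoring
    rows without a response); raw RTs are retained on the image for
    onset-versus-RT statistics.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be odd and >= 1")
    if width > image.n_rows:
        raise ValueError(f"width {width} exceeds the {image.n_rows} image rows")
    half = width // 2
    data = _truncated_mean_rows(image.data, half)
    out = image.replace(data=data,
                        smoothing={**image.smoothing, "moving_avg_width": width})
    if smooth_rts:
        rts = image.rts
        sm = np.empty_like(rts)
        for i in range(len(rts)):
            lo, hi = max(0, i - half), min(len(rts), i + half + 1)
            chunk = rts[lo:hi]
            finite = chunk[np.isfinite(chunk)]
            sm[i] = finite.mean() if finite.size else np.nan
        out.rts_smoothed = sm
    return out


def gaussian_smooth_rows(image: ERPImage, sd: float = 2.0) -> ERPImage:
    """Gaussian smoothing along the trial axis, for visualization only.

    The kernel is truncated at ±3 SD and renormalised (also at the
    edges).  Onset estimation must never consume this output.
    """
    if sd <= 0:
        raise ValueError("sd must be > 0")
    n = image.n_rows
    half = max(int(np.ceil(3.0 * sd)), 0)
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd) ** 2)
    k /= k.sum()
    out = np.empty_like(image.data, dtype=float)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        w = k[lo - i + half: hi - i + half]
        w = w / w.sum()
        out[i] = w @ image.data[lo:hi]
    return image.replace(data=out,
                         smoothing={**image.smoothing, "gaussian_sd_trials": sd})


def sort_by_rt(image: DifferenceImage, use_smoothed: bool = True
               ) -> DifferenceImage:
    """Sort rows ascending by (smoothed) RT; ties keep original order.

    Rows without an RT (no go-response) are excluded first and logged.
    """
    key = image.rts_smoothed if (use_smoothed and image.rts_smoothed is not None) \
        else image.rts
    key = np.asarray(key, dtype=float)
    has_rt = np.isfinite(key)
    n_drop = int((~has_rt).sum())
    if n_drop:
        logger.info("sort_by_rt: excluding %d row(s) without a go-response", n_drop)
    idx = np.flatnonzero(has_rt)[np.argsort(key[has_rt], kind="stable")]
    out = image.replace(
        data=image.data[idx], trial_ids=image.trial_ids[idx],
        rts=image.rts[idx], order="rt", order_key=key[idx],
        rts_smoothed=None if image.rts_smoothed is None else image.rts_smoothed[idx],
    )
    for attr in ("contra_trial_ids", "p45_ipsi", "p45_contra"):
        val = getattr(image, attr, None)
        if val is not None:
            setattr(out, attr, np.asarray(val)[idx])
    return out
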