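"""Wavelet denoising of single-trial evoked responses.

Two-stage procedure: (1) the average evoked response is decomposed with
an undecimated (stationary, shift-invariant) wavelet transform at a
small number of scales (four by default) and the coefficients that
characterise the evoked response are selected by thresholding against a
robust noise estimate from the pre-stimulus baseline; (2) every single
trial is decomposed with the same transform, coefficients outside the
keep-mask are zeroed, and the inverse transform returns the denoised
trial.  Because background EEG is broadband while the evoked response
concentrates on few coarse coefficients, this separates the evoked
response from the background activity without shifting single-trial
latencies (the transform is undecimated, so there is no subsampling
phase to shift onsets).

The wavelet family defaults to a quadratic B-spline biorthogonal
wavelet; the thresholding constant ``k`` defaults to 3 with the
per-scale noise sigma estimated as MAD(baseline coefficients)/0.6745.
Both are configuration, not constants, and are recorded on the fitted
denoiser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pywt

__all__ = ["WaveletDenoiser", "fit_denoiser", "apply_denoiser"]


def _pad_scheme(n: int, level: int) -> tuple[int, int]:
    """(left pad, total padded length): reflect-pad both sides.

    The stationary transform is circular, so without padding the epoch's
    late activity wraps into the pre-stimulus baseline coefficients and
    corrupts the noise estimate there.  Both sides are padded by at
    least half the coarsest filter footprint, rounded so the total is a
    multiple of 2**level.
    """
    block = 2 ** level
    pad = ((3 * block + block - 1) // block) * block          # >= 3 blocks
    total = ((n + 2 * pad + block - 1) // block) * block
    return pad, total


def _swt(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    """Stationary wavelet transform; returns [cA_L, cD_L, ..., cD_1]."""
    return pywt.swt(x, wavelet, level=level, trim_approx=True, norm=False)


@dataclass
class WaveletDenoiser:
    """Fitted keep-masks for the stationary wavelet transform.

    ``masks[0]`` applies to the coarsest approximation, ``masks[1:]`` to
    the detail coefficients from coarsest to finest scale.
    """

    wavelet: str
    n_scales: int
    masks: list[np.ndarray]
    thresholds: list[float]
    fit_len: int
    pad_left: int
    pad_len: int
    threshold_k: float
    n_baseline: int
    provenance: dict = field(default_factory=dict)

    # -- serialization ---------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "wavelet": self.wavelet,
            "n_scales": self.n_scales,
            "masks": [np.flatnonzero(m).tolist() for m in self.masks],
            "mask_len": self.pad_len,
            "thresholds": list(map(float, self.thresholds)),
            "fit_len": self.fit_len,
            "pad_left": self.pad_left,
            "pad_len": self.pad_len,
            "threshold_k": self.threshold_k,
            "n_baseline": self.n_baseline,
            "provenance": self.provenance,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "WaveletDenoiser":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        masks = []
        for idx in d["masks"]:
            m = np.zeros(d["mask_len"], dtype=bool)
            m[np.asarray(idx, dtype=int)] = True
            masks.append(m)
        return cls(wavelet=d["wavelet"], n_scales=d["n_scales"], masks=masks,
                   thresholds=d["thresholds"], fit_len=d["fit_len"],
                   pad_left=d["pad_left"], pad_len=d["pad_len"],
                   threshold_k=d["threshold_k"],
                   n_baseline=d["n_baseline"], provenance=d.get("provenance", {}))


def _prepare(trace: np.ndarray, pad_left: int, pad_len: int) -> np.ndarray:
    x = np.asarray(trace, dtype=float)
    right = pad_len - pad_left - len(x)
    return np.pad(x, (pad_left, right), mode="reflect")


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0 or not mask.any():
        return mask
    out = mask.copy()
    for i in np.flatnonzero(mask):
        out[max(0, i - radius): i + radius + 1] = True
    return out


def fit_denoiser(average_erp: np.ndarray, n_scales: int = 4,
                 threshold_k: float = 3.0, wavelet: str = "bior2.2",
                 n_baseline: int | None = None, dilate: bool = False,
                 noise_rows: np.ndarray | None = None,
                 n_effective: float | None = None,
                 provenance: dict | None = None) -> WaveletDenoiser:
    """Learn the coefficient keep-mask from the average evoked response.

    A coefficient of the average is kept when its magnitude exceeds
    ``threshold_k`` times the scale's robust noise sigma (MAD-based,
    MAD/0.6745).  ``n_baseline`` gives the number of leading
    (pre-stimulus) samples treated as signal-free; it defaults to a
    quarter of the trace.

    Noise calibration: by default sigma is estimated from the average's
    own baseline coefficients at each scale.  At coarse scales those
    coefficients are few and heavily autocorrelated (a handful of
    independent values), which makes the resulting masks unstable.  When
    the single trials that produced the average are passed as
    ``noise_rows``, sigma is instead estimated from their pooled
    baseline coefficients and divided by ``sqrt(n_effective)`` (the
    effective number of independent trials in the average; defaults to
    ``len(noise_rows)``, and should be reduced when the rows were
    smoothed across trials beforehand).  This estimates the same
    quantity from hundreds of values instead of a handful.

    With ``dilate``, each scale's mask is extended to every coefficient
    whose filter support overlaps a supra-threshold one.  This
    counteracts the amplitude shrinkage of reconstructing from a strict
    coefficient subset of a redundant transform, at the cost of passing
    more single-trial background noise; the default leaves it off to
    keep single-trial traces maximally quiet for onset reading.
    """
    x = np.asarray(average_erp, dtype=float)
    min_len = 2 ** n_scales
    if x.ndim != 1 or len(x) < min_len:
        raise ValueError(f"average ERP must be 1-D with length >= {min_len}")
    if n_baseline is None:
        n_baseline = max(len(x) // 4, 1)
    pad_left, pad_len = _pad_scheme(len(x), n_scales)
    coeffs = _swt(_prepare(x, pad_left, pad_len), wavelet, n_scales)
    flen = len(pywt.Wavelet(wavelet).dec_lo)
    # coeffs = [cA_L, cD_L, ..., cD_1]; the level determines the
    # upsampled filter footprint at that scale
    levels = [n_scales] + list(range(n_scales, 0, -1))
    base = slice(pad_left, pad_left + n_baseline)
    row_coeffs = None
    if noise_rows is not None:
        noise_rows = np.atleast_2d(np.asarray(noise_rows, dtype=float))
        if noise_rows.shape[1] != len(x):
            raise ValueError("noise_rows must match the average's length")
        row_coeffs = [_swt(_prepare(r, pad_left, pad_len), wavelet, n_scales)
                      for r in noise_rows]
        if n_effective is None:
            n_effective = len(noise_rows)
    masks, thresholds = [], []
    for j, (c, lev) in enumerate(zip(coeffs, levels)):
        if row_coeffs is not None:
            pool = np.concatenate([rc[j][base] for rc in row_coeffs])
            sigma = np.median(np.abs(pool - np.median(pool))) / 0.6745
            sigma /= np.sqrt(n_effective)
        else:
            sigma = np.median(np.abs(c[base] - np.median(c[base]))) / 0.6745
        thr = threshold_k * sigma
        mask = np.abs(c) > thr
        if dilate:
            mask = _dilate(mask, (flen - 1) * 2 ** (lev - 1) // 2)
        masks.append(mask)
        thresholds.append(float(thr))
    return WaveletDenoiser(
        wavelet=wavelet, n_scales=n_scales, masks=masks, thresholds=thresholds,
        fit_len=len(x), pad_left=pad_left, pad_len=pad_len,
        threshold_k=threshold_k, n_baseline=n_baseline,
        provenance=provenance or {})


def apply_denoiser(denoiser: WaveletDenoiser, trials: np.ndarray) -> np.ndarray:
    """Zero all coefficients outside the keep-mask and invert the transform.

    *trials* is one trace (1-D) or a trials x time matrix whose time
    length must equal the denoiser's fit length.
    """
    arr = np.asarray(trials, dtype=float)
    single = arr.ndim == 1
    mat = arr[np.newaxis, :] if single else arr
    if mat.shape[1] != denoiser.fit_len:
        raise ValueError(
            f"trial length {mat.shape[1]} != denoiser fit length {denoiser.fit_len}")
    out = np.empty_like(mat)
    lo = denoiser.pad_left
    for i, row in enumerate(mat):
        coeffs = _swt(_prepare(row, lo, denoiser.pad_len), denoiser.wavelet,
                      denoiser.n_scales)
        kept = [c * m for c, m in zip(coeffs, denoiser.masks)]
        rec = pywt.iswt(kept, denoiser.wavelet, norm=False)
        out[i] = rec[lo: lo + denoiser.fit_len]
    return out[0] if single else out
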