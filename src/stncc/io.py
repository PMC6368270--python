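"""File formats: raw float32 binary + JSON sidecar for arrays, TSV for tables.

Continuous recordings and epoch arrays are stored as little-endian
float32 with a JSON sidecar carrying rate, channel labels and shape;
event, trial, ground-truth and result tables are tab-separated text.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousEEG, EpochSet

__all__ = [
    "save_continuous", "load_continuous", "save_epochs", "load_epochs",
    "save_table", "load_table", "sha256_of",
]


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_continuous(eeg: ContinuousEEG, directory: str | Path,
                    stem: str = "continuous") -> dict[str, Path]:
    """Write data as <stem>.f32 + <stem>.json sidecar + <stem>_events.tsv."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bin_path = d / f"{stem}.f32"
    np.asarray(eeg.data, dtype="<f4").tofile(bin_path)
    sidecar = {
        "rate_hz": eeg.rate,
        "channels": list(eeg.channel_labels),
        "n_samples": int(eeg.n_samples),
        "dtype": "<f4",
        "order": "channels_major",
        "units": "uV",
    }
    json_path = d / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar, indent=1))
    ev_path = save_table(eeg.events, d / f"{stem}_events.tsv")
    return {"data": bin_path, "sidecar": json_path, "events": ev_path}


def load_continuous(directory: str | Path, stem: str = "continuous") -> ContinuousEEG:
    d = Path(directory)
    meta = json.loads((d / f"{stem}.json").read_text())
    data = np.fromfile(d / f"{stem}.f32", dtype=meta["dtype"]).reshape(
        len(meta["channels"]), meta["n_samples"])
    events = load_table(d / f"{stem}_events.tsv")
    return ContinuousEEG(data=data.astype(float), rate=meta["rate_hz"],
                         channel_labels=tuple(meta["channels"]), events=events)


def save_epochs(epochs: EpochSet, directory: str | Path,
                stem: str = "epochs") -> dict[str, Path]:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    bin_path = d / f"{stem}.f32"
    np.asarray(epochs.data, dtype="<f4").tofile(bin_path)
    sidecar = {
        "shape": list(epochs.data.shape),
        "time_axis_ms": epochs.time_axis.tolist(),
        "channels": list(epochs.channel_labels),
        "trial_ids": np.asarray(epochs.trial_ids).tolist(),
        "baseline_ms": list(epochs.baseline_window),
        "dtype": "<f4",
        "units": "uV",
    }
    json_path = d / f"{stem}.json"
    json_path.write_text(json.dumps(sidecar))
    return {"data": bin_path, "sidecar": json_path}


def load_epochs(directory: str | Path, stem: str = "epochs") -> EpochSet:
    d = Path(directory)
    meta = json.loads((d / f"{stem}.json").read_text())
    data = np.fromfile(d / f"{stem}.f32", dtype=meta["dtype"]).reshape(meta["shape"])
    return EpochSet(data=data.astype(float),
                    time_axis=np.asarray(meta["time_axis_ms"]),
                    channel_labels=tuple(meta["channels"]),
                    trial_ids=np.asarray(meta["trial_ids"]),
                    baseline_window=tuple(meta["baseline_ms"]))
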