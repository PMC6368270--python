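"""In-memory containers for continuous recordings and epoched data.

Amplitudes are microvolts throughout; times are milliseconds relative to
the start of the recording (continuous data) or to visual stimulus onset
(epoched data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_TYPES = ("stim", "tms", "response")


@dataclass
class ContinuousEEG:
    """Multichannel continuous recording with an event table.

    ``data`` is channels x samples (µV); ``events`` is a DataFrame with
    columns ``type`` (stim/tms/response), ``time_ms`` and ``trial``.
    The ``stim`` event marks trial alignment time for every trial —
    including TMS-only trials, where it is the nominal (absent) visual
    onset the epoch is time-locked to.
    """

    data: np.ndarray
    rate: float
    channel_labels: tuple[str, ...]
    events: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data rows")
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if np.isnan(self.data).any():
            raise ValueError("continuous data must not contain missing samples")
        bad = set(self.events["type"]) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unknown event types: {sorted(bad)}")
        tmax = self.n_samples / self.rate * 1000.0
        t = self.events["time_ms"].to_numpy(float)
        if len(t) and (t.min() < 0 or t.max() > tmax):
            raise ValueError("event times must lie within the record")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.rate * 1000.0

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label) if isinstance(
                self.channel_labels, list) else list(self.channel_labels).index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}; have {list(self.channel_labels)}")

    def get_channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]


@dataclass
class EpochSet:
    """Trials x channels x time array, time-locked to visual stimulus onset."""

    data: np.ndarray
    time_axis: np.ndarray
    channel_labels: tuple[str, ...]
    trial_ids: np.ndarray
    baseline_window: tuple[float, float] = (-200.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x time")
        n_tr, n_ch, n_t = self.data.shape
        if n_ch != len(self.channel_labels):
            raise ValueError("channel count mismatch")
        if n_t != len(self.time_axis):
            raise ValueError("time axis length mismatch")
        if n_tr != len(self.trial_ids):
            raise ValueError("trial_ids length mismatch")
        if len(np.unique(self.trial_ids)) != len(self.trial_ids):
            raise ValueError("trial_ids must be unique")
        if n_t and not (self.time_axis.min() <= 0.0 <= self.time_axis.max()):
            raise ValueError("time axis must contain 0 (stimulus onset)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def rate(self) -> float:
        dt = np.diff(self.time_axis)
        return 1000.0 / dt[0]

    def channel_index(self, label: str) -> int:
        try:
            return list(self.channel_labels).index(label)
        except ValueError:
            raise KeyError(f"no channel {label!r}")

    def get_channel(self, label: str) -> np.ndarray:
        """Trials x time matrix for one channel."""
        return self.data[:, self.channel_index(label), :]

    def select_trials(self, mask_or_ids) -> "EpochSet":
        """Subset by boolean mask (per epoch) or by trial id array."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = np.flatnonzero(np.isin(self.trial_ids, arr))
        return EpochSet(self.data[idx], self.time_axis, self.channel_labels,
                        self.trial_ids[idx], self.baseline_window)


@dataclass
class ERPImage:
    """Single-trial matrix (trials x time) for one channel.

    ``rts`` holds each row's reaction time in ms (NaN when the trial had
    no go-response); ``rts_smoothed`` is filled once a moving average has
    been applied.  ``smoothing`` records every smoothing step applied.
    """

    data: np.ndarray
    time_axis: np.ndarray
    channel: str
    trial_ids: np.ndarray
    rts: np.ndarray
    order: str = "none"                      # none | p45 | rt
    order_key: np.ndarray | None = None
    rts_smoothed: np.ndarray | None = None
    smoothing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.rts = np.asarray(self.rts, dtype=float)
        self.trial_ids = np.asarray(self.trial_ids)
        if self.data.ndim != 2:
            raise ValueError("image must be trials x time")
        if self.data.shape[1] != len(self.time_axis):
            raise ValueError("time axis length mismatch")
        if self.data.shape[0] != len(self.rts) or self.data.shape[0] != len(self.trial_ids):
            raise ValueError("row metadata length mismatch")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def replace(self, **kw) -> "ERPImage":
        import dataclasses
        if "smoothing" not in kw:
            kw["smoothing"] = dict(self.smoothing)
        return dataclasses.replace(self, **kw)


@dataclass
class DifferenceImage(ERPImage):
    """ERP image whose rows are matched ipsilateral - contralateral pairs.

    Row RTs come from the ipsilateral member of each pair.
    """

    contra_trial_ids: np.ndarray | None = None
    p45_ipsi: np.ndarray | None = None
    p45_contra: np.ndarray | None = None
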