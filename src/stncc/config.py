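"""Session and analysis configuration.

The defaults encode the experimental design being emulated: a go/no-go
visual detection task with single-pulse occipital TMS delivered 90 ms
after stimulus onset, four interleaved trial conditions (visual target
alone, TMS ipsilateral to the target, TMS contralateral, TMS alone),
a 0--3 subjective visibility rating after every trial, and 32-channel
EEG (30 scalp sites of the 10--20 system plus two ocular channels).

Evoked components are modelled as Gaussian bumps.  For a bump of peak
amplitude ``A`` (µV), peak latency ``mu`` (ms) and width ``sigma``
(ms), the latency at which it crosses a detection threshold ``thr``
is ``mu - sigma * sqrt(2 * ln(|A| / thr))``; :func:`onset_to_peak_latency`
inverts this so component defaults can be calibrated to a nominal
onset latency rather than a peak latency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

#: 30 scalp electrodes (10-20 system) followed by two ocular channels.
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "POz", "PO4", "O1",
)
EOG_CHANNELS: tuple[str, ...] = ("EOG1", "EOG2")
DEFAULT_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + EOG_CHANNELS

CONDITIONS: tuple[str, ...] = ("vis_only", "ipsi", "contra", "tms_only")
#: Conditions in which a visual target is physically present.
TARGET_CONDITIONS: tuple[str, ...] = ("vis_only", "ipsi", "contra")
#: Conditions in which a TMS pulse is delivered.
TMS_CONDITIONS: tuple[str, ...] = ("ipsi", "contra", "tms_only")

COMPONENT_KINDS: tuple[str, ...] = ("P45", "VAN_posterior", "VAN_frontal", "LP")


def onset_to_peak_latency(onset_ms: float, amplitude_uv: float,
                          width_ms: float, threshold_uv: float = 1.5) -> float:
    """Peak latency of a Gaussian bump whose threshold crossing is at *onset_ms*."""
    a = abs(amplitude_uv)
    if a <= abs(threshold_uv):
        raise ValueError("amplitude must exceed the threshold for an onset to exist")
    return onset_ms + width_ms * math.sqrt(2.0 * math.log(a / abs(threshold_uv)))


def width_for_onset(onset_ms: float, peak_latency_ms: float,
                    amplitude_uv: float, threshold_uv: float = 1.5) -> float:
    """Gaussian width (ms) placing the threshold crossing at *onset_ms* given the peak."""
    a = abs(amplitude_uv)
    if a <= abs(threshold_uv):
        raise ValueError("amplitude must exceed the threshold for an onset to exist")
    return (peak_latency_ms - onset_ms) / math.sqrt(2.0 * math.log(a / abs(threshold_uv)))


@dataclass
class ComponentParams:
    """One evoked component, modelled as a Gaussian bump.

    ``scalp_weights`` maps channel label -> multiplicative gain; channels
    absent from the map receive zero.  ``rating_scaled`` marks components
    that index conscious perception: their amplitude is scaled linearly by
    visibility rating (rating/3, so rating 0 gives exactly zero).
    """

    peak_latency_ms: float
    peak_amplitude_uv: float
    width_ms: float
    scalp_weights: dict[str, float]
    latency_jitter_sd_ms: float = 0.0
    amplitude_sd_uv: float = 0.0
    rating_scaled: bool = False

    def validate(self, channels: tuple[str, ...]) -> None:
        if self.width_ms <= 0:
            raise ValueError("component width_ms must be > 0")
        unknown = set(self.scalp_weights) - set(channels)
        if unknown:
            raise ValueError(
                f"scalp_weights reference channels not in the montage: {sorted(unknown)}"
            )


def expected_rating_contrast(behavior: "BehaviorParams | None" = None) -> float:
    """Expected (ipsi - contra) visibility-rating difference divided by 3.

    Because conscious-correlate amplitudes scale linearly with rating/3,
    this is the factor by which the ipsilateral-contralateral difference
    wave dilutes a component's full-visibility amplitude.
    """
    bp = behavior if behavior is not None else BehaviorParams()

    def e(probs):
        return sum(r * p for r, p in enumerate(probs))

    return (e(bp.p_rating["ipsi"]) - e(bp.p_rating["contra"])) / 3.0


def default_component_params() -> dict[str, ComponentParams]:
    """Default component set.

    VAN (posterior/frontal) is the negative awareness-related difference
    peaking at 166/216 ms; LP the late positivity over 300--400 ms; P45
    the prominent TMS-evoked potential peaking 45 ms after the pulse
    (135 ms after visual onset with the 90 ms pulse delay).

    Amplitudes of the rating-scaled components are calibrated to the
    *difference wave*: with the default behavior parameters, the expected
    ipsilateral-contralateral difference carries a -3 µV posterior VAN
    crossing the -1.5 µV onset threshold at 150 ms, a -2.5 µV frontal
    VAN, and a +4 µV LP crossing +1.5 µV at 320 ms.  The stored
    ``peak_amplitude_uv`` is therefore the full-visibility (rating 3 vs.
    nothing) amplitude, i.e. the difference-wave target divided by the
    expected rating contrast.
    """
    contrast = expected_rating_contrast()
    van_width = width_for_onset(150.0, 166.0, -3.0)     # ≈ 13.6 ms
    lp_width = width_for_onset(320.0, 350.0, 4.0)       # ≈ 21.4 ms
    posterior = {"Pz": 1.0, "POz": 1.0, "P3": 0.8, "P4": 0.8, "PO3": 0.9,
                 "PO4": 0.9, "PO7": 0.6, "O1": 0.7, "P7": 0.5, "P8": 0.5,
                 "CP1": 0.4, "CP2": 0.4}
    frontal = {"Fz": 1.0, "F3": 0.7, "F4": 0.7, "FC1": 0.6, "FC2": 0.6,
               "Fp1": 0.3, "Fp2": 0.3}
    centro_parietal = {"Pz": 1.0, "CP1": 0.8, "CP2": 0.8, "Cz": 0.7,
                       "P3": 0.8, "P4": 0.8, "POz": 0.7, "CP5": 0.5,
                       "CP6": 0.5, "PO3": 0.5, "PO4": 0.5}
    occipital = {"O1": 1.0, "PO7": 0.9, "PO3": 0.9, "POz": 0.8, "Pz": 0.6,
                 "PO4": 0.7, "P7": 0.5, "P3": 0.4, "P4": 0.3}
    return {
        "P45": ComponentParams(135.0, 5.0, 10.0, occipital,
                               latency_jitter_sd_ms=5.0, amplitude_sd_uv=1.5),
        "VAN_posterior": ComponentParams(166.0, -3.0 / contrast, van_width,
                                         posterior, latency_jitter_sd_ms=10.0,
                                         amplitude_sd_uv=0.5, rating_scaled=True),
        "VAN_frontal": ComponentParams(216.0, -2.5 / contrast, van_width, frontal,
                                       latency_jitter_sd_ms=10.0,
                                       amplitude_sd_uv=0.5, rating_scaled=True),
        "LP": ComponentParams(350.0, 4.0 / contrast, lp_width, centro_parietal,
                              latency_jitter_sd_ms=15.0,
                              amplitude_sd_uv=0.8, rating_scaled=True),
    }


@dataclass
class NoiseModel:
    """Background EEG: Gaussian noise with a 1/f^exponent amplitude spectrum."""

    exponent: float = 1.0
    sd_uv: float = 10.0

    def validate(self) -> None:
        if self.sd_uv < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class BehaviorParams:
    """Generative model of ratings, go/no-go responses and reaction times.

    ``p_rating`` gives p(rating | condition) over ratings 0..3;
    ``p_go_given_rating`` the go probability per rating; RTs are
    lognormal with a per-rating median (ms) and a common log-scale SD.
    """

    p_rating: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "vis_only": (0.02, 0.05, 0.13, 0.80),
            "ipsi": (0.03, 0.05, 0.12, 0.80),
            "contra": (0.50, 0.25, 0.15, 0.10),
            "tms_only": (0.90, 0.06, 0.03, 0.01),
        }
    )
    p_go_given_rating: tuple[float, float, float, float] = (0.05, 0.60, 0.90, 0.97)
    rt_median_ms: dict[int, float] = field(
        default_factory=lambda: {0: 360.0, 1: 340.0, 2: 320.0, 3: 300.0}
    )
    rt_log_sd: float = 0.15

    def validate(self) -> None:
        for cond, probs in self.p_rating.items():
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r} in p_rating")
            if len(probs) != 4 or any(p < 0 or p > 1 for p in probs):
                raise ValueError("p_rating rows must be 4 probabilities in [0, 1]")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"p_rating[{cond!r}] must sum to 1")
        if any(p < 0 or p > 1 for p in self.p_go_given_rating):
            raise ValueError("p_go_given_rating must lie in [0, 1]")
        if any(m <= 0 for m in self.rt_median_ms.values()):
            raise ValueError("rt medians must be positive")
        if self.rt_log_sd < 0:
            raise ValueError("rt_log_sd must be >= 0")


@dataclass
class SessionConfig:
    """Full specification of one synthetic TMS-EEG session."""

    raw_rate: float = 5000.0
    target_rate: float = 250.0
    n_trials_per_condition: dict[str, int] = field(
        default_factory=lambda: {"vis_only": 192, "ipsi": 192,
                                 "contra": 192, "tms_only": 96}
    )
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    tms_delay_ms: float = 90.0
    component_params: dict[str, ComponentParams] = field(
        default_factory=default_component_params
    )
    noise_model: NoiseModel = field(default_factory=NoiseModel)
    behavior_params: BehaviorParams = field(default_factory=BehaviorParams)
    tms_artifact_amplitude_uv: float = 2000.0
    tms_artifact_duration_ms: float = 2.0
    iti_range_ms: tuple[float, float] = (1400.0, 1800.0)
    epoch_span_ms: tuple[float, float] = (-200.0, 500.0)
    pad_s: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.raw_rate <= 0 or self.target_rate <= 0:
            raise ValueError("rates must be > 0")
        ratio = self.raw_rate / self.target_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("target_rate must divide raw_rate evenly")
        counts = self.n_trials_per_condition
        if set(counts) - set(CONDITIONS):
            raise ValueError(f"unknown conditions in trial counts: {set(counts) - set(CONDITIONS)}")
        if any(n < 0 for n in counts.values()) or sum(counts.values()) <= 0:
            raise ValueError("trial counts must be >= 0 with at least one trial")
        if not (self.epoch_span_ms[0] < self.tms_delay_ms < self.epoch_span_ms[1]):
            raise ValueError("tms_delay_ms must lie within the epoch span")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        for kind, comp in self.component_params.items():
            if kind not in COMPONENT_KINDS:
                raise ValueError(
                    f"unknown component kind {kind!r}; valid kinds: {COMPONENT_KINDS}")
            comp.validate(tuple(self.channels))
        self.noise_model.validate()
        self.behavior_params.validate()

    # -- YAML round trip -------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["channels"] = list(self.channels)
        d["iti_range_ms"] = list(self.iti_range_ms)
        d["epoch_span_ms"] = list(self.epoch_span_ms)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionConfig":
        d = dict(d)
        if "component_params" in d:
            d["component_params"] = {
                k: v if isinstance(v, ComponentParams) else ComponentParams(**v)
                for k, v in d["component_params"].items()
            }
        if "noise_model" in d and not isinstance(d["noise_model"], NoiseModel):
            d["noise_model"] = NoiseModel(**d["noise_model"])
        if "behavior_params" in d and not isinstance(d["behavior_params"], BehaviorParams):
            bp = dict(d["behavior_params"])
            if "p_rating" in bp:
                bp["p_rating"] = {k: tuple(v) for k, v in bp["p_rating"].items()}
            if "p_go_given_rating" in bp:
                bp["p_go_given_rating"] = tuple(bp["p_go_given_rating"])
            if "rt_median_ms" in bp:
                bp["rt_median_ms"] = {int(k): float(v) for k, v in bp["rt_median_ms"].items()}
            d["behavior_params"] = BehaviorParams(**bp)
        for key in ("channels", "iti_range_ms", "epoch_span_ms"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class AnalysisConfig:
    """Parameters of the analysis chain, with the study's constants as defaults."""

    mute_window_ms: float = 15.0
    mute_pre_samples: int = 3
    mute_anchor_ms: float = 10.0
    highpass_hz: float = 0.05
    lowpass_hz: float = 40.0
    reject_sd: float = 5.0
    baseline_ms: tuple[float, float] = (-200.0, 0.0)
    channels_of_interest: tuple[str, ...] = ("Pz", "Fz")
    onset_channel: str = "Pz"
    moving_avg_width: int = 5
    gaussian_sd_trials: float = 2.0
    wavelet: str = "bior2.2"
    n_scales: int = 4
    denoise_k: float = 3.0
    van_threshold_uv: float = -1.5
    lp_threshold_uv: float = 1.5
    min_duration_ms: float = 20.0
    exclude_pre_tms: bool = True
    perm_n: int = 10000
    perm_alpha: float = 0.001
    rt_motor_ms: float = 40.0

    def validate(self) -> None:
        if self.mute_window_ms <= 0 or self.mute_anchor_ms <= 0:
            raise ValueError("mute window and anchor spans must be > 0")
        if not (0 < self.highpass_hz < self.lowpass_hz):
            raise ValueError("need 0 < highpass < lowpass")
        if self.moving_avg_width < 1 or self.moving_avg_width % 2 == 0:
            raise ValueError("moving_avg_width must be odd and >= 1")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.min_duration_ms <= 0:
            raise ValueError("min_duration_ms must be > 0")
        if not (0 < self.perm_alpha < 1):
            raise ValueError("perm_alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        for key in ("baseline_ms", "channels_of_interest"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg
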