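"""Generate a synthetic TMS-EEG session and inspect its ground truth.

The generator emulates a go/no-go visual detection task with occipital
TMS 90 ms after stimulus onset: four interleaved conditions, evoked
components (P45, posterior/frontal VAN, LP) whose amplitudes scale with
the trial's visibility rating, a 2 ms pulse artifact, and 1/f noise.
"""

import numpy as np

from stncc import SessionConfig, simulate_session

cfg = SessionConfig(
    raw_rate=1000.0,            # reduced from the 5 kHz default for speed
    n_trials_per_condition={"vis_only": 48, "ipsi": 48,
                            "contra": 48, "tms_only": 24},
    seed=7,
)
eeg, trials, truth = simulate_session(cfg)

print(f"recording: {len(eeg.channel_labels)} channels x {eeg.n_samples} "
      f"samples at {eeg.rate:.0f} Hz ({eeg.duration_ms / 1000:.0f} s)")
print(f"events: {eeg.events['type'].value_counts().to_dict()}")
print("\nmean visibility rating by condition (contralateral TMS suppresses):")
print(trials.groupby("condition")["rating"].mean().round(2).to_string())

seen = truth[np.isfinite(truth["true_van_onset_ms"])]
print(f"\n{len(seen)}/{len(truth)} trials carry a VAN whose noiseless "
      f"waveform meets the -1.5 uV / 20 ms onset criterion")
print(f"median true VAN onset {seen['true_van_onset_ms'].median():.0f} ms "
      f"(full-visibility trials cross earlier than partially seen ones)")
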