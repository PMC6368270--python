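"""Preprocess a session and measure the grand-average NCC difference wave.

Chain: TMS mute-window interpolation (15 ms cut, cubic fit) -> resample
to 250 Hz -> one-pass Blackman windowed-sinc filtering (0.05-40 Hz,
half-amplitude cutoffs) -> -200..500 ms epochs with baseline correction
-> 5 SD peak-amplitude epoch rejection.  The TMS-evoked potential
(TMS-only condition) is subtracted from the TMS conditions, and the
ipsilateral - contralateral difference is measured in the canonical
VAN and LP windows.
"""

import numpy as np

from stncc import (
    LP_WINDOW, SessionConfig, VAN_POSTERIOR, average_erp, epoch,
    preprocess_continuous, reject_epochs, simulate_session,
    subtract_tms_only, window_mean,
)

cfg = SessionConfig(
    raw_rate=1000.0,
    n_trials_per_condition={"vis_only": 64, "ipsi": 64,
                            "contra": 64, "tms_only": 32},
    seed=3,
)
eeg, trials, _ = simulate_session(cfg)
clean = preprocess_continuous(eeg, target_rate=cfg.target_rate)
epochs = epoch(clean)
epochs, removed = reject_epochs(epochs, sd_threshold=5.0)
print(f"epochs: {epochs.n_trials} kept, {len(removed)} rejected (5 SD rule)")

cond = dict(zip(trials["trial"], trials["condition"]))
erp = {c: average_erp(epochs, np.array([t for t in epochs.trial_ids
                                        if cond[t] == c]))
       for c in ("ipsi", "contra", "tms_only")}
visual_ipsi = subtract_tms_only(erp["ipsi"], erp["tms_only"])
diff = erp["ipsi"] - erp["contra"]

pz = list(epochs.channel_labels).index("Pz")
van = window_mean(diff[pz], epochs.time_axis, VAN_POSTERIOR)
lp = window_mean(diff[pz], epochs.time_axis, LP_WINDOW)
print(f"Pz ipsi-contra difference: VAN window (166 +/- 6 ms) {van:+.2f} uV, "
      f"LP window (300-400 ms) {lp:+.2f} uV")
print("negative-then-positive is the NCC signature: the awareness "
      "negativity precedes the late positivity")
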