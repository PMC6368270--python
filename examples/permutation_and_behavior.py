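"""Sign-flip permutation test on difference waves, and behavioral summaries.

The single-trial differences are paired (ipsilateral minus matched
contralateral trial), so the null is built by randomly flipping each
row's sign; the two-tailed p-value uses the +1 correction and the strict
alpha = 0.001 stands in for multiple-comparison correction across time.
"""

import numpy as np

from stncc import (
    SessionConfig, behavioral_probabilities, rt_summaries,
    sign_flip_permutation_test, significant_spans, simulate_behavior,
)
from stncc.pipeline import session_difference_image

cfg = SessionConfig(raw_rate=1000.0, seed=5,
                    n_trials_per_condition={"vis_only": 0, "ipsi": 96,
                                            "contra": 96, "tms_only": 48})
img, t = session_difference_image(cfg, channel="Pz")
res = sign_flip_permutation_test(img.data, alpha=0.001, n_perm=5000, seed=5,
                                 time_axis=t, channel="Pz")
print(f"Pz: {int(res.significant.sum())}/{len(t)} timepoints significant "
      f"at p <= 0.001 ({res.n_permutations} sign-flip permutations)")
for lo, hi in significant_spans(res):
    sign = "+" if res.mean_diff[np.searchsorted(t, lo)] > 0 else "-"
    print(f"  {lo:.0f}..{hi:.0f} ms ({sign})  "
          "(negative span = VAN, positive span = LP)")

table = simulate_behavior(SessionConfig(seed=5))
beh = behavioral_probabilities(table)
print("\np(go | rating) in the contralateral condition:")
print(beh["p_go_given_rating"]["contra"].round(3).to_string())
print("\nmedian RT (ms) of go-trials per condition:")
rts = rt_summaries(table)
print(rts[rts["rating"] == "all"][
    ["condition", "n", "median_rt_ms", "sd_rt_ms"]].round(1).to_string(index=False))
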