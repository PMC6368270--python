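# stncc — single-trial timing of the neural correlates of visual consciousness

`stncc` is a Python library for asking *when* the electrophysiological
correlates of visual consciousness arise relative to a person's own
speeded report of seeing, at the level of single trials.

The experimental design it analyses: a go/no-go detection task in which
single-pulse TMS is delivered over early visual cortex 90 ms after a
brief visual target. When the pulse is **contralateral** to the target
it suppresses conscious perception; an **ipsilateral** pulse is the
physically matched control. Each trial yields a go/no-go response, a
reaction time, and a 0–3 visibility rating. Two EEG difference
components index consciousness:

- **VAN** (visual awareness negativity): a negative ipsilateral −
  contralateral difference, posterior around 166 ms, frontal around
  216 ms;
- **LP / P300** (late positivity): a broad positive difference over
  300–400 ms.

The question is whether these components *precede* the report. With
median RTs near 300 ms and ~40 ms of motor execution inside the RT, a
correlate that only begins near or after RT − 40 ms is too late to be
the process that enables conscious perception to guide behaviour.

Because grand averages cannot order events within a trial, the package
implements a single-trial chain:

1. **Preprocessing** — the TMS pulse artifact is excised (15 ms mute
   window starting 3 samples before the pulse) and bridged with a
   least-squares cubic; the recording is resampled to 250 Hz and
   filtered with one-pass Blackman windowed-sinc FIRs (0.05 and 40 Hz
   half-amplitude cutoffs); −200…500 ms epochs are baseline-corrected
   and epochs whose peak amplitude exceeds mean + 5 SD are rejected.
2. **Matched single-trial differences** — ipsilateral and contralateral
   trial counts are equated, both sets are sorted by the amplitude of
   the prominent TMS-evoked potential **P45** (measured 129–141 ms),
   and rank-i trials are subtracted, so trials with comparable
   TMS-evoked responses cancel. Rows are smoothed with a 5-trial
   moving average.
3. **Wavelet denoising** — a stationary (undecimated, so latencies are
   not shifted) wavelet transform at 4 scales; coefficients that
   characterise the average difference wave are selected by
   thresholding at k·σ̂ (k = 3, σ̂ a robust MAD-based noise estimate)
   and only those are retained in each single trial.
4. **Onset estimation** — VAN onset = earliest sample < −1.5 µV
   sustained ≥ 20 ms after stimulus onset; LP onset = earliest sample
   > +1.5 µV sustained ≥ 20 ms after the VAN onset (or after stimulus
   onset when no VAN was found). Onsets before the pulse (90 ms) are
   flagged as noise-driven.
5. **Statistics** — per-timepoint sign-flip permutation tests on the
   paired differences (two-tailed, α = 0.001, +1-corrected p-values);
   electrode-wise paired t-tests on window means with Benjamini–
   Hochberg FDR at 5%; behavioural probability and RT summaries.

No public dataset exists for this paradigm, so the package ships a
first-class **synthetic session generator** (`stncc.synth`) with known
ground truth: Gaussian-bump components whose amplitudes scale linearly
with the visibility rating (an unseen trial carries exactly zero VAN/LP),
a biphasic ≥1 mV pulse artifact, 1/f background noise, and lognormal
RTs. Every stage of the chain is tested against it.

## Worked example

```bash
python examples/onsets_vs_rt.py
```

```
rows analysed: 192 (pooled from 2 sessions)
median VAN onset: 128 ms (n=131)
median LP onset:  304 ms (n=130)
median ipsilateral RT: 305 ms (~265 ms after motor-execution correction)
LP onsets after the manual RT: 53.4% of trials
```

Read: across 192 matched single-trial difference waves (two small
sessions pooled), the awareness negativity begins ~130–150 ms after the
stimulus — well before the ~265 ms at which the motor command for the
report must have been issued — while the late positivity begins around
300 ms and follows the overt report on half of the trials. That is the
package's core result structure: VAN early enough to cause conscious
perception, LP too late.

The other scripts in `examples/` each demonstrate one capability:
session generation with ground truth, preprocessing + grand-average
window measures, difference-image denoising, and permutation/behavioural
statistics.

A thin CLI wraps the pipeline for shell use:

```bash
stncc run --config cfg.yaml --out run/     # simulate + analyse + report.json
stncc simulate --out session/ --seed 3     # write a raw synthetic session
stncc report run/                          # print a finished run's report
```

`run/report.json` carries the onset medians, RT summaries, permutation
spans and trial accounting; `run/manifest.json` records the config
snapshot, seeds and SHA-256 digests of every output, and re-running the
same config and seed reproduces the digests byte for byte.

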