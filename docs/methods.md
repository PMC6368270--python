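# Methods

This note documents the models, estimators and numerical choices behind
`stncc`, what the synthetic data generator does and does not emulate,
and the known limitations of the onset estimator.

## The generative model of a session

A session interleaves four conditions — visual target alone
(`vis_only`, 192 trials), target + ipsilateral TMS (`ipsi`, 192),
target + contralateral TMS (`contra`, 192), and TMS alone (`tms_only`,
96) — with inter-trial intervals drawn uniformly from 1.4–1.8 s and
stimulus onsets aligned to the 250 Hz analysis grid. EEG is synthesised
at `raw_rate` (5 kHz by default; tests and examples use 1 kHz, stated
explicitly in their configs) on 30 scalp + 2 ocular channels.

**Behaviour.** Each trial draws a visibility rating from
p(rating | condition), a go/no-go response from p(go | rating), and —
for go trials — a lognormal RT with a per-rating median (300 ms at full
visibility, slower for dimmer percepts; log-scale SD 0.15, matching the
right-skew of empirical RT distributions). The defaults make
ipsilateral vision essentially intact (80% rating 3) and contralateral
vision strongly suppressed (50% rating 0); these are plausible
settings, not values fitted to any dataset.

**Evoked components** are Gaussian bumps `A·exp(−(t−μ)²/2σ²)`,
truncated at ±3σ, with per-trial Gaussian jitter on amplitude and peak
latency. P45 (peak 135 ms, i.e. 45 ms after the pulse) appears in every
TMS trial. VAN (posterior peak 166 ms, frontal 216 ms) and LP (peak
350 ms) are the conscious-perception correlates: their amplitude scales
linearly with rating/3, so a rating-0 trial carries exactly zero. A
bump of amplitude A and width σ crosses a threshold θ at
`μ − σ·√(2·ln(|A|/θ))` and stays beyond it for twice that half-width;
this closed form defines each trial's ground-truth onset and is how the
defaults are calibrated: the **expected ipsilateral − contralateral
difference wave** carries a −3 µV posterior VAN crossing −1.5 µV at
150 ms and a +4 µV LP crossing +1.5 µV at 320 ms. Because the
difference dilutes full-visibility amplitudes by the expected rating
contrast (≈ 0.61 under the default behaviour), the stored
full-visibility amplitudes are the targets divided by that contrast.

**Artifact and noise.** The TMS pulse artifact is one 2 ms sine cycle
of 2 mV, sampled at bin midpoints so coarse rates do not alias it to
zero. Background noise is Gaussian with a 1/f amplitude-squared
spectrum (exponent 1, RMS 10 µV — typical broadband scalp EEG). The
generator does **not** emulate ocular or muscle artifacts (the 5 SD
epoch rejection therefore fires rarely on synthetic data), volume
conduction (channel topographies are fixed weight maps), hemispheric
lateralisation, or a motor potential around the response. Passing
tests consequently show the chain is correct under its stated model,
not that it is robust to every artifact class in human recordings.

## Preprocessing

The mute window (15 ms starting 3 samples before the pulse) is replaced
by a degree-3 polynomial fitted by least squares to 10 ms anchor spans
on each side; the abscissa is centred and scaled before the fit for
conditioning, and samples outside the window are returned untouched.
Least squares over anchors was chosen over endpoint interpolation for
noise robustness; the anchor span is a free parameter.

Filters are windowed-sinc FIRs (Blackman window), designed with a
transition bandwidth of 25% of the cutoff (floor 0.05 Hz) and the
Blackman length rule N ≈ 5.5·rate/Δf. Cutoffs are half-amplitude
(−6 dB): the high-pass at 0.05 Hz and low-pass at 40 Hz are each
applied **once** (a forward-backward pass would square the response and
move the half-amplitude point). By default the linear-phase group
delay is compensated after the single pass; a strictly causal mode
exists, but at 250 Hz the 0.05 Hz high-pass is ~27,500 taps (~55 s of
group delay), which would destroy event latencies, so delay
compensation is the default. Resampling is polyphase with the built-in
anti-alias filter.

Epochs span −200…500 ms (176 samples at 250 Hz, 0 on the grid);
baseline correction subtracts each channel's mean over [−200, 0) ms.
Epoch rejection removes epochs whose peak absolute amplitude exceeds
mean + 5 SD of the per-epoch peak distribution — a deterministic
replacement for visual artifact screening, applied in channel space
(independent-component screening is out of scope).

## The single-trial difference image

Counts are equated by uniform random removal from the larger condition
(seeded), then both conditions are sorted ascending by P45 amplitude
(mean over 129–141 ms, a 12 ms window mirroring the VAN convention) and
paired rank-by-rank, so that contralateral trials with strong
TMS-evoked responses are subtracted from ipsilateral trials with strong
ones. Row RTs come from the ipsilateral member. The 5-trial moving
average across rows uses truncated, renormalised edge windows (a
constant image is therefore exactly preserved; exact column-mean
preservation is impossible for a local row-stochastic smoother and is
not claimed). RTs are smoothed with the same window for sorting, with
raw RTs retained for all onset-versus-RT statistics. Gaussian row
smoothing (SD 2 trials, kernel truncated at ±3 SD and renormalised) is
visualisation-only and is never fed to onset estimation. Window-mean
measures use closed sample-centre intervals so counts are deterministic
on the 4 ms grid.

## Wavelet denoising

A stationary (undecimated) wavelet transform at 4 scales,
quadratic-B-spline biorthogonal family (`bior2.2`), both configurable.
The undecimated transform was chosen because onsets are read from
single trials: decimation would shift single-trial latencies. Traces
are reflect-padded on both sides before the transform — the transform
is circular, and without padding the epoch's late activity wraps into
the pre-stimulus baseline coefficients. The keep-mask marks
coefficients of the **average** difference wave whose magnitude exceeds
k·σ̂ per scale (k = 3); single trials are transformed, masked, and
inverted.

σ̂ is a MAD/0.6745 estimate of the scale's noise in the average. Two
estimators are provided. The default, average-only estimator uses the
average's own baseline coefficients; at coarse scales the baseline
contains only a handful of independent coefficients, so this estimator
is noisy. When the single trials behind the average are supplied
(`noise_rows`), σ̂ is instead the pooled MAD of their baseline
coefficients divided by √n_effective; the pipeline uses this with
n_effective = n_rows / moving-average width, since the across-trial
smoothing leaves roughly that many independent rows. Masks are still
selected on the average's coefficients. An optional mask dilation
(off by default) extends each scale's mask across the filter footprint;
it counteracts the amplitude shrinkage of subset reconstruction in a
redundant transform at the price of passing more background into the
single trials.

## Onset estimation and its bias

The criterion is threshold + duration: VAN onset is the first sample of
the earliest run with amplitude strictly below −1.5 µV lasting ≥ 20 ms
(≥ 5 consecutive samples at 250 Hz; a run of n samples counts as n
sample periods), searched from stimulus onset; LP uses +1.5 µV and
starts at the VAN onset, falling back to stimulus onset when no VAN was
found. Thresholds, duration and the strict inequality are all
configurable for sensitivity analyses. Onsets before the TMS pulse are
flagged and excluded from summary medians by default — the pre-pulse
signal is identical in both conditions, so such onsets are necessarily
noise-driven.

First-crossing estimators are biased early under noise, by roughly the
residual noise SD divided by the waveform's slope at threshold. On
noiseless synthetic sessions the full chain recovers the configured
onsets exactly (VAN 152 ms, LP 320 ms on the 4 ms grid). Under the
default 10 µV background, the VAN's steep rise keeps its median within
a few ms of 150, but the LP rises at only ~0.07 µV/ms at threshold, and
its detected onsets spread early — including a distinct spurious early
cluster in rows without a VAN, the same two-cluster structure visible
in real single-trial LP onset data. Pooled over three default sessions
the median detected LP onset sits ≈ 20 ms before the configured 320 ms.
This is a property of the estimator under the configured noise, not of
the implementation; the threshold rule is retained because it is the
analysis under study (curve-fitting onset estimators are a non-goal).
Session-level 1/f noise also leaves each session's difference wave with
a random slow offset of ~0.7 µV SD (cross-trial correlated noise does
not average out at 1/√n), which is why single-session onset medians
wobble by tens of ms and the parameter-recovery analyses pool several
seeded sessions, mirroring multi-participant pooling.

## Statistics

The permutation test flips the sign of each paired difference row
(ipsi/contra label exchange within a pair is a sign flip), 10,000
permutations by default, two-tailed p with the +1 correction so p ≥
1/(n_perm+1) — necessary for validity at the strict α = 0.001, which
itself stands in for multiple-comparison correction across timepoints.
The test requires exchangeable rows, so the pipeline feeds it the
un-smoothed difference rows; the across-trial moving average would
correlate adjacent rows and inflate false positives. Electrode-wise
comparisons are paired t-tests on window means (posterior VAN 166 ± 6
ms, frontal VAN 216 ± 6 ms, LP 300–400 ms) with Benjamini–Hochberg
step-up FDR at q = 0.05; zero-variance electrodes degenerate to p = 1
(zero mean) or p = 0 (constant nonzero difference). Behavioural
probabilities are empirical frequencies with explicit denominators
(empty cells are reported absent, never 0/0); RT medians are on raw
milliseconds with dispersion on both raw and log scales.

## Configuration and reproducibility

All constants of the procedure (15 ms mute, 90 ms pulse delay, ±1.5 µV,
20 ms, α = 0.001, q = 0.05, 4 scales, 5-trial smoothing, Gaussian SD 2)
live as named defaults on `SessionConfig`/`AnalysisConfig`, which
validate their invariants and round-trip through YAML. Every
stochastic step takes a seed; `run_pipeline` writes a manifest with the
config snapshot and SHA-256 digests of all outputs, and identical
config + seed reproduces identical digests. Analyses in the test suite
and acceptance script synthesise at 1 kHz raw rate (stated in their
configs) and the study's full trial counts.
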