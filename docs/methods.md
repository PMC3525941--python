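# Methods

This note records the models, numerical conventions, and design choices
behind `streambci`, and what the synthetic-data results do and do not show
about real EEG.

## Stimulus model

A trial interleaves two periodic tone streams presented dichotically: 8
left-ear stimuli and 7 right-ear stimuli (15 events, all within 5 s of the
first onset). Timing constants per condition:

| condition | left SOA (s) | right SOA (s) | right first onset (s) |
|-----------|--------------|---------------|------------------------|
| FP        | 0.4922       | 0.4922        | 0.2461                 |
| DP        | 0.4922       | 0.5469        | 0.1094                 |
| FP500     | 0.500        | 0.500         | 0.250                  |

Time zero is the first left-stream onset; the visual cue period appears as
negative time in trial-level analyses (gaze traces start at −2 s). In DP the
right-minus-left onset lag grows by 54.7 ms per index, which is the
"drifting phase" property.

Tones are 150 ms sawtooth waves (512 Hz left / 768 Hz right) with 5 ms
raised-cosine ramps. The sawtooth is synthesized additively from harmonics
up to Nyquist, which is a clean band-limited (anti-aliased) construction;
the original hardware's anti-aliasing method is unknown, and any reasonable
choice is equivalent for the analyses here. Standard tones are
amplitude-modulated to 100% depth by a raised sine, `0.5·(1 − cos 2π f_am
t)`; the modulation frequencies are defined as 256/6 and 256/7 Hz — exactly
6 and 7 samples per period at the 256 Hz EEG rate, 42.67/36.57 Hz to printed
precision. Target positions are drawn uniformly without replacement among
stream indices ≥ 2 (the first two stimuli of each stream are always
standards); target counts, when not specified, are uniform on {1, 2, 3} per
stream.

## Synthetic EEG

Each stimulus evokes the same biphasic response: one negated sine cycle over
0.4 s, negative peak at 100 ms, positive peak at 300 ms, unit peak
amplitude. (Non-default peak latencies are honoured by piecewise-linear
phase warping of the sine; the default is the exact single cycle.) The
response amplitude is multiplied by `attended_gain` (default 1.2) when the
stimulus belongs to the attended stream. Per trial, an impulse train at the
event samples is convolved with the wavelet, projected to the electrodes by
a fixed per-channel gain vector (a fronto-central topography peaking at Cz
and Fz for the default 16-channel montage; unit gain for other channel
counts), and summed with pink noise.

Pink noise is synthesized spectrally (Gaussian coefficients with amplitude
∝ 1/√f, flattened below the lowest resolvable bin, zero DC) and rescaled to
its target SD exactly. The target SD per channel is `sd_ratio` (default
2.0) times that channel's *noiseless-signal* SD measured over the
stimulation interval — from each trial's first stimulus onset to its last
wavelet offset — so lead-in/tail padding does not dilute the reference SD.
Trials are laid out back to back with 0.5 s lead-in and 1.0 s tail; these
paddings only need to exceed the filter's settling scale and the epoch
window.

The generator deliberately omits latency jitter (default 0), component
habituation, blink/EMG artifacts, inter-channel noise correlation, and any
nonstationarity. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration under the assumed signal model, not expected
performance levels on real EEG, where noise is correlated across channels
and responses vary.

Gaze traces (60 Hz, −2 s to +4.5 s around sound onset) approach
±`drift_gain` exponentially from cue onset with a 1 s time constant plus
white noise; the vertical channel is fixation noise. This is a plumbing
model for the confound audit, not a model of oculomotor behaviour.

Cohorts draw per-subject `attended_gain` from U(1.1, 1.3), `sd_ratio` from
U(1.5, 2.5) and `drift_gain` from U(0, 0.3): modest, symmetric spreads
around the canonical 1.2 / 2.0 operating point chosen once to emulate
between-subject variability. Each subject gets 6 runs of 20 trials per
condition, matching the within-subject study layout (5 scored runs = 100
online trials after the first, feedback-free run).

## Decoding chain

* **Filter.** Butterworth band-pass 0.1–8 Hz, order 6 (scipy `butter(6, …)`
  on the band), causal (`sosfilt`) for online decoding; the visualization
  variant is 0.1–45 Hz applied forward–backward (`sosfiltfilt`, zero
  phase). Filter state runs continuously across a recording, mimicking
  real-time operation; designs whose poles come within 1e−6 of the unit
  circle are rejected as numerically unusable.
* **Epochs.** 600 ms windows starting at each retained onset —
  `floor(0.6·fs)` = 153 samples at 256 Hz, half-open `[onset, onset+0.6 s)`
  — after discarding the first two stimuli per stream (6 left + 5 right
  epochs per trial).
* **Running difference.** Per trial, X_Δ = running mean of right-locked
  epochs − running mean of left-locked epochs, updated after every epoch
  (11 snapshots per FP trial). Before a stream has contributed its first
  retained epoch its running mean is a zero matrix; the final snapshot
  equals the batch difference exactly. Running averages reset at trial
  boundaries. The unequal 6-vs-5 epoch counts enter as plain per-stream
  means, no reweighting.
* **Whitening.** Σ is the mean over training epochs of the per-epoch
  spatial covariance (time mean removed per epoch, n−1 denominator);
  W = (Σ + ridge·I)^(−1/2) by symmetric eigendecomposition, ridge
  defaulting to 1e−6·tr(Σ)/n_channels. Whitened training epochs have
  identity mean spatial covariance up to the ridge.
* **Classifier.** L2-penalized linear logistic regression (scikit-learn
  lbfgs, tol 1e−12) on the flattened whitened features divided by a single
  global RMS scale. The scalar (not per-dimension) scale is deliberate: it
  keeps the penalized objective invariant under invertible channel
  mixings, which whitening absorbs up to an orthogonal rotation — a
  property the test suite checks to 1e−4. Default λ = 1.0 on this
  standardized scale (an optional 5-fold CV over λ ∈ 10^{−2..2} is
  provided); the bias is not penalized. Positive output ↔ attend-right
  (natural for X_Δ = right − left); an exact zero is broken toward right.
* **Incremental protocol.** Run k ≥ 2 is scored by the model trained on
  runs 1..k−1 pooled; run 1 (no feedback) only seeds training. Six runs of
  20 trials yield 100 scored trials per condition.
* **Control signal.** EMA `y_k = (1−d)x_k + d·y_{k−1}` with d = 0.5 — the
  unit-DC-gain reading of a "decay factor of 0.5", chosen so smoothing
  preserves scale — then a causal 8th-order 3 Hz Butterworth low-pass
  (bypassed with a warning when the update rate cannot resolve it), then
  affine gain/offset. Gain and offset have no canonical values and are
  exposed as configuration.

## Statistics

d_a uses sample SDs (n−1). Signed r² is sign(r)·r² of the point-biserial
correlation with attend-right positive. ROI windows (ms): N1 70–125,
P2 150–240, P3 250–310 for grand averages; Δ1 50–90, Δ2 120–190, Δ3 200–265
for difference-wave sensitivity. The exact Wilcoxon signed-rank test drops
zero differences (Wilcoxon's original treatment), mid-ranks ties, and for
n ≤ 25 computes the exact two-sided p as the null mass of |W⁺ − E[W⁺]| at
least as large as observed, via dynamic programming over the sign-flip
distribution (identical to enumerating all 2ⁿ assignments); beyond that a
tie-corrected normal approximation is used. Fisher's exact test is
two-sided by the probability-mass rule. Spearman's rho is the Pearson
correlation of midranks with an exact full-permutation p for n ≤ 9 and the
usual asymptotic p otherwise. Hit rates are reported to one decimal place.

## Study-level analyses

The **SNR simulation** generates, per condition, n single-channel trials
per class (default 1000) at the canonical parameters (gain 1.2, noise SD
ratio 2.0), runs the online chain, and computes the per-sample d_a of the
final X_Δ between attend-right and attend-left trials. "FP advantage" is
summarized as max_t |d_a^FP| / max_t |d_a^DP| — the maximum over epoch
samples, the natural single-feature reading of a peak-sensitivity ratio.
At these parameters the ratio lands around 2.1–2.5 across seeds, i.e.
above 1 and below the ~3× ceiling expected from the stimulus-overlap
argument.

**Backward playback** reverses the recorded samples while keeping the event
table, destroying the stimulus–response alignment but preserving signal
statistics; decoding the reversed recordings estimates empirical chance.
The **gaze audit** computes peak |signed r²| over trial time for raw
horizontal gaze, for gaze passed through the EEG preprocessing chain
(band-pass at the gaze rate, stimulus-locked difference averaging), and for
the preprocessed Cz channel, then Spearman-correlates each peak statistic
with decoding accuracy across subjects.

## Problem sizes and determinism

The test suite and the acceptance script scale simulations to desk sizes
chosen for tight sampling error at interactive runtimes: the chance-level
calibration trains on 600 and evaluates on 600 null trials (binomial SE
≈ 2 percentage points), and the SNR simulation uses the full 1000 noise
instances per class. All generators are driven by explicit
`numpy.random.Generator` seeds; every analysis is bit-reproducible under a
fixed seed, and experiment outputs carry a config hash alongside the seed.

## Known limitations

Single dipole-free source with fixed topography; noise independent across
channels; no artifacts or nonstationarity; the gaze model is phenomenological;
the continuous-control game itself is out of scope (its published hit/miss
counts are analysed with the exact-test layer instead). The regularization
strength and covariance ridge are package defaults, not values recovered
from any recorded dataset.
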