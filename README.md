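# streambci

A tested, reusable implementation of the analysis chain behind a two-class
**auditory streaming brain–computer interface (BCI)**: a system that decodes
which of two simultaneous tone streams — one per ear — a listener is
attending to, from the event-related potentials (ERPs) the streams evoke in
the EEG.

Such systems matter for people with severe paralysis who cannot rely on
vision: the user answers a yes/no question purely by listening. The package
is aimed at BCI researchers who want to prototype and stress-test the
stimulus design and decoding chain on synthetic data before (or alongside)
subject experiments.

## What is implemented

**Stimulus scheduling and audio** (`streambci.schedule`). One trial is 8
left-ear tones (512 Hz sawtooth, 150 ms) interleaved with 7 right-ear tones
(768 Hz). In the *fixed-phase* (FP) design both streams share a 492.2 ms
stimulus-onset asynchrony and sit half a period apart; in the
*drifting-phase* (DP) design the right stream's period is 546.9 ms so the
relative phase drifts. Standard tones are amplitude-modulated at 42.67 /
36.57 Hz (exactly 6 / 7 EEG samples per modulation period at 256 Hz);
target tones, which the listener counts, are unmodulated.

**Synthetic data** (`streambci.synthgen`). Each stimulus evokes a one-cycle
biphasic wavelet (negative peak 100 ms, positive peak 300 ms), 20% larger
when attended; the source is projected to a 16-channel montage and buried in
pink (1/f) noise with twice the signal's standard deviation. Optional gaze
traces drift toward the attended side.

**Decoding** (`streambci.preprocess`, `streambci.decode`). The online chain
band-pass filters 0.1–8 Hz (Butterworth, order 6, causal), cuts 600 ms
epochs at every stimulus onset (skipping the first two per stream), and
forms the running difference of right-locked and left-locked average
epochs,

```
X_Δ = X_R − X_L .
```

A linear logistic-regression classifier, L2-regularized after **symmetric
whitening** (premultiplication by Σ^(−1/2), the inverse matrix square root
of the mean spatial covariance of the training epochs), scores X_Δ; the
sign of the final output is the predicted direction of attention. An
exponential moving average plus an 8th-order 3 Hz low-pass turns the raw
output into a continuous control signal.

**Statistics** (`streambci.stats`). The sensitivity index

```
d_a = (μ_att − μ_unatt) / sqrt((σ²_att + σ²_unatt) / 2) ,
```

signed r² (signed squared point-biserial correlation), grand averages with
N1/P2/P3 and difference-wave regions of interest, and exact small-n tests
(Wilcoxon signed-rank by sign-flip enumeration, Fisher's exact test,
Spearman correlation with permutation p).

**Study-level analyses** (`streambci.experiments`): the single-channel
FP-vs-DP signal-to-noise simulation, a within-subject cohort comparison
with incremental retraining, chance-level estimation by backward playback,
and the gaze-confound audit.

## Worked example

```python
import numpy as np
import streambci as sb
from streambci.preprocess import ONLINE_FILTER

rng = np.random.default_rng(0)
cond = sb.build_condition("FP")
trials = [sb.make_trial(cond, s, rng) for s in ("left", "right") * 40]
rec = sb.simulate_recording(trials, sb.ERPModel(attended_gain=1.2),
                            sb.NoiseModel(sd_ratio=2.0), rng=rng)
epochs = sb.extract_epochs(sb.bandpass(rec, ONLINE_FILTER))
labels = {tid: tr.attended for tid, tr in enumerate(trials)}
results = sb.AttentionDecoder.from_epochs(epochs, labels).fit()
print(results.summary())
```

```
Attention decoder (whitened L2 logistic regression)
====================================================
trials:            80  (left 40 / right 40)
feature shape:     16 channels x 153 samples
lambda (L2):       1
covariance ridge:  1.41e-07
bias:              +1.3048
|weights|:         1.1573
training accuracy: 100.0%
```

The decoder separates the 80 simulated trials perfectly in-sample (held-out
accuracy on such data is lower but far above the 50% chance level; the test
suite checks both). The FP-vs-DP simulation quantifies why the fixed-phase
design is preferred:

```python
res = sb.snr_simulation(sb.SimulationConfig(n_instances=1000, seed=0))
print(f"FP peak |d_a| = {res['peak_da']['FP']:.3f}")
print(f"DP peak |d_a| = {res['peak_da']['DP']:.3f}")
print(f"FP:DP ratio   = {res['ratio']:.2f}")
```

```
FP peak |d_a| = 2.744
DP peak |d_a| = 1.294
FP:DP ratio   = 2.12
```

i.e. at these noise levels the fixed-phase design roughly doubles — and can
approach triple — the peak single-feature sensitivity of the drifting-phase
design.

A thin CLI mirrors these analyses
(`streambci snr-sim | simulate-cohort | evaluate | playback-chance |
gaze-audit`); run `streambci --help`.

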