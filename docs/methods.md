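# Methods

This note documents the models, defaults and numerical choices behind
`ssveptag`, and what its synthetic-data tests do and do not establish
about real EEG.

## Task model

A trial is: 400 ms fade-in (both gratings 0 → 50% contrast, cue shown
during the fade), 800 ms baseline at 50/50, then a 2000 ms evidence
phase in which the target grating steps to 50 + d and the non-target to
50 − d, where d is the titrated **marginal contrast** (percent). All
contrast time courses are generated at the display's 100 Hz frame rate;
millisecond values snap to the 10 ms frame grid. Reciprocity
(contrasts sum to 100%) holds at every frame after the fade-in.

Pulses last 150 ms, start at one of {180, 260, 340, 420, 500} ms after
evidence onset, and are instantaneous at both edges: *reverse* swaps
the two contrasts, *gap* sets both to 50%, and *positive* adds the
differential evidence (2d) to the target and subtracts it from the
non-target — so a 60/40 trial pulses to 80/20 and both reverse and
positive pulses have a summed contrast change of 40%. A positive pulse
therefore requires d ≤ 50/3; larger differentials raise an error. The
16 pulse conditions (3 types × 5 onsets + none) are represented equally
in every session.

Cue composition is a session-level constraint (valid = 4 × invalid,
invalid = neutral, remainder of a non-divisible count going to valid so
directional cues stay 80% predictive asymptotically); cue labels are
paired with pulse-cell slots by independent shuffles so the two factors
stay unconfounded, and tag frequency (20/25 Hz) and target tilt are
counterbalanced within every cue × pulse cell to within one trial. The
gratings' starting phase alternates by a half cycle on every trial;
only the EEG forward model consumes this flag.

The replacement mechanism follows the task rules literally: a response
before evidence onset appends an exact replica to the current block; a
response before pulse onset adds a triple (immutable replica plus two
mutable trials drawn uniformly without replacement from the other
cue × pulse-onset combinations) to the end-of-session extra block, with
later early responses swapping a mutable trial for a replica unless
none remains or more than 20% of the extra block already shares the
pulse type — in which case a fresh triple is added. Note that with a
small extra block the 20% rule triggers whenever the new trial's pulse
type is already present; this is a property of the rule as stated, not
of the implementation.

## Adaptive procedures

The simulated observer is a Weibull 2AFC psychometric function
parameterised directly by its 70%-correct threshold (slope β = 3.5,
lapse 2%, guess rate 0.5); the scale parameter is derived so that
P(correct at threshold) = 0.70 exactly. A separate logistic choice
function (width 4% contrast) models the perceptual "flicker bias"
toward the 20 Hz grating as the 25 Hz contrast boost needed for
indifference.

Staircases use a fixed 8% step halved at each reversal with a 1% floor.
The one-up-two-down staircase starts at 100% differential and the
session procedure terminates it after four reversals or 50 trials (60
for the one-up-one-down bias staircase). Because a descent from 100%
spends reversals on lapses far above threshold, the four-reversal
estimate is a poor measure of where the *rule* converges; when the
package needs the convergence point itself (tests, the acceptance
script) it runs the rule for 400 trials with the reversal cap lifted
and averages the reversal levels after discarding the first four
(standard burn-in practice). The one-up-two-down equilibrium is
P(correct)² = 0.5 → 70.7% correct; the one-up-one-down equilibrium is
the 50% choice point.

QUEST is a grid posterior (256 points, log-spaced 0.5–100% differential)
over the threshold of the same Weibull family, with a lognormal prior
centred at 20% (SD 0.5 log10 units). Trials are placed at the current
posterior-median threshold and the estimate is the posterior median:
with 60 trials the posterior is right-skewed and the posterior *mean*
overshoots the 70% point by about two accuracy points, while the median
is calibrated (checked against the observer's known psychometric
function). Estimates above 65% raise the insufficient-practice flag.
The 30-trial verification block nudges the differential by the QUEST
posterior margin toward 70% and requests a rerun when accuracy deviates
by five percentage points or more.

## Synthetic EEG forward model

Trial records are 34-channel (32 scalp + VEOG pair), 512 Hz, spanning
−1800 to +2080 ms around evidence onset. Scalp positions come from the
standard 10-05 montage projected to the unit sphere; component
topographies are spherical Gaussians (SSVEP at Oz, mu-beta at C3/C4,
alpha at POz, blinks frontal).

* **SSVEP**: one sinusoid per grating at its tag frequency, instantaneous
  amplitude = `ssvep_gain` (0.02 µV/% by default) × the grating's
  effective contrast. A cue-dependent *encoding gain* scales the
  contrast differential around 50%: the default configuration is
  neutral (all gains 1.0), and switching on `exposure_ramp` lowers the
  invalid-cue gain linearly to 0.7 by end of session — the generator's
  mechanism for a sensory expectation effect that emerges with task
  exposure. Harmonics are omitted: the pipeline reads only the
  fundamental.
* **Mu-beta**: 8–30 Hz band-passed noise whose amplitude drops by
  `mb_lateralization_uv` (0.3 µV) contralateral to the cued hand from
  cue onset, and ramps down by a further 0.5 µV contralateral to the
  executed response over the final 400 ms before the response
  (desynchronisation = preparation).
* **Alpha**: 8–14 Hz band noise scaled per cue condition; the neutral
  cue gets 0.8 × the cued amplitude (greater desynchronisation =
  greater engagement without predictive information).
* **Noise**: per-channel 1/f (exponent 1) noise, SD 1.5 µV. This SNR is
  deliberately optimistic — it was calibrated once so that single-trial
  marginal-SSVEP sign recovery in the 680–975 ms window is ≳95%, which
  makes single-trial ground-truth tests meaningful. Real EEG is far
  noisier; passing recovery tests here demonstrates correctness of the
  extraction chain, not expected single-trial performance on real data.
* **Blinks**: Poisson events (0.05 Hz) of ±300 µV on the VEOG pair with
  ~30% frontal scalp propagation, so they trip the 250 µV VEOG
  rejection rule but not (by themselves) the 100 µV scalp rule.

Behaviour: accuracy is Bernoulli with base 70% shifted on the logit
scale per cue (+0.184 valid, −0.219 invalid — the accuracy deltas are
treated as logit-scale contrasts); RT is a shifted lognormal
(≈0.85 s mean) with additive per-cue shifts of −0.043/+0.085 s for
correct and +0.084/−0.047 s for error responses.

A second, measure-level generator (`simulate_analysis_table`) draws the
per-trial scalars of the analysis table directly (marginal SSVEP =
encoding gain × 0.12 µV/% × marginal contrast + subject intercept +
N(0, 1) noise; per-bin marginal contrasts default to the titration
trajectory 16.3, 13.1, 11.4, 11.5, 11.4%). It exists so the statistics
battery can be calibrated over hundreds of replicates without paying
for full EEG synthesis; the EEG chain is exercised end-to-end by its
own recovery tests at smaller n.

## Preprocessing

Fixed order: detrend + low-pass → bad channels → interpolation →
average reference → epoching/baseline → rejection → CSD. The low-pass
is a zero-phase (symmetric, 257-tap Hamming) FIR with −6 dB at 40 Hz.
Bad channels are flagged by a two-sided robust z (> 3.5) on log channel
variance, with zero-variance channels flagged outright and a warning
when more than 20% of channels are flagged. Interpolation and the CSD
use the spherical-spline Legendre series (m = 4, λ = 1e−5, 50 terms);
CSD output is in µV/m² up to the unit head-radius scale. Epoch spans
are cue-locked −1700:500 ms and evidence-locked −400:2000 ms relative
to evidence onset (baselines −1400:−1200 and −600:−400; the
evidence-locked baseline window precedes the epoch span, so it is
measured on the continuous record before cropping), and response-locked
−600:400 ms cut from surviving evidence-locked epochs. All windows are
half-open `[start, end)` in ms. Rejection (|VEOG difference| > 250 µV
or any scalp channel > 100 µV) runs independently for cue-locked and
evidence-locked epochs.

## Spectral extraction

The STFT uses a rectangular taper, amplitude-scaled so a unit on-bin
sinusoid reads 1. At 512 Hz a 400 ms window is realised as 205 samples,
so bins sit at 512/205 ≈ 2.4976 Hz and the 20/25 Hz tags are within
0.03 Hz of bin centres; the resulting leakage is below 0.25% and the
noise-free extraction error below 0.5%. Windows advance in 50 ms steps
(start samples rounded independently to avoid drift) and map to their
midpoints. SSVEP normalization subtracts the mean of the two nearest
bins on each side of the tag bin, skipping both tag bins. Mu-beta is
the 8–30 Hz mean amplitude excluding the two tag bins; alpha is the
8–14 Hz mean with a 360 ms window. Channel combination averages the
signal before the transform (averaging amplitude after the transform is
available as a switch). Electrode selection ranks an occipital pool by
mean marginal SSVEP in 200:1800 ms (top two, ties by pool order) and a
central pool per hemisphere by the rank-sum of response-locked
contra-vs-ipsi amplitude difference and pre-response slope.

Known limitation: at pulse edges the instantaneous contrast step rings
across neighbouring bins, and the neighbour-bin normalization subtracts
part of that ringing, so window-level fidelity is bounded near the
discontinuities (pooled correlation with the injected contrast
difference ≈0.98 on pulse trials vs ≈0.995 on no-pulse trials).

## Statistics

All models are trial-level with a subject intercept and no other random
effects. Identity-link models are REML linear mixed models; fixed
effects are tested by Wald F with residual denominator df — the engine
provides no Satterthwaite approximation, so the output labels the df
method (`residual`; `residual-ols` after a singular-variance fallback to
OLS). Binary responses use a logistic model with per-subject *fixed*
intercepts (no frequentist GLMM engine is available) and Wald
chi-square tests, labelled `wald-fixed-intercept`. Pairwise condition
contrasts are uncorrected, matching the analysis plan; no other
multiple-testing correction is applied. Task exposure enters as the
per-subject chronological quintile (1–5, remainder trials to the
earliest bins) treated as a numeric covariate. Inclusion rules:
RT > 100 ms for behaviour and evidence-locked SSVEP models, RT > 680 ms
for the SSVEP→behaviour models, no RT filter for pre-evidence mu-beta
and alpha. Pulse type and tag frequency enter the behaviour and
evidence-locked SSVEP models as control fixed effects. The
−752:−214 ms and −752:−215 ms printed baseline windows select identical
midpoints on the 50 ms STFT grid and are implemented as one window.

The model registry (`analyses.yaml`) maps each analysis to its formula,
link, inclusion rule and focal term; the test suite asserts the
registry's completeness. Type-I calibration runs the full battery on
500 null-generator replicates (6 subjects × 192 trials — sized so the
calibration completes in minutes while leaving ≈6500 focal p-values)
and requires the pooled false-positive rate at α = 0.05 to lie in
[0.03, 0.07]. The exposure-interaction recovery check uses 12 subjects
× 2000 trials (full-study trial counts) and requires detection in at
least 80 of 100 replicates.

## What the tests show — and don't

Because the generator injects known ground truth at generous SNR, green
tests establish that the pipeline's arithmetic is right (amplitudes are
recovered, signs are correct, selection finds the injected channels,
the battery is calibrated and powered under its own assumptions). They
do not establish that real scalp EEG supports single-trial SSVEP
read-outs at these reliabilities, that the Gaussian-topography forward
model captures volume conduction, or that real expectation effects
follow the injected linear exposure ramp.
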