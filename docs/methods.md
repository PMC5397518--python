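# Methods

This note documents the models, conventions and numerical choices behind
`gait5m`, in the order data flows through the package.

## Synthetic trial model

The generator emulates an instrumented 5-m walking trial: ≥ 3 s quiet
standing, an acoustic start signal, a reaction delay, gait initiation,
n steps, a terminal positioning step, and quiet standing again, all sampled
at 100 Hz.

**Velocity envelope.** Forward (AP) velocity follows a raised-cosine ramp
up over the first `accel_phase_steps` steps, a plateau, and a raised-cosine
ramp down over the final `decel_phase_steps` steps plus the positioning
step. The peak velocity is solved analytically so that the enclosed area
equals the track length (5 m); for the default self-selected profile this
gives ≈ 1.38 m/s, and the fast condition (one step fewer, 15% shorter
steps) comes out ≈ 1.9 m/s.

**Step cycles.** Heel strikes are spaced by per-step durations drawn from
N(mean, sd) (defaults 0.55 ± 0.02 s, ≈ 109 steps/min). A zero-mean
sinusoidal oscillation at step frequency rides on the AP velocity; its
per-step integral is exactly zero, so it moves no net distance. VT
acceleration carries a per-step cosine peaking at each heel strike plus a
³ m/s² Gaussian transient (σ = 12 ms, ≈ 60 ms wide) at each strike; ML
acceleration and the three angular velocities carry step- or
stride-periodic oscillations. Cycle amplitudes are constant across the
counted steps and taper only over the positioning step: cadence-linked
trunk sway does not scale with forward speed, and the final steps of a real
walk keep near-full step dynamics even as forward velocity drops.

**Exact discretization.** AP acceleration is emitted as the exact discrete
inverse of trapezoidal integration of the constructed velocity, so
integrating the emitted signal reproduces the ground-truth velocity and
displacement to float precision. The cost is a bounded alternating Nyquist
component of order dt²·|v‴| ≈ 3·10⁻³ m/s², far below the default sensor
noise (0.05 m/s² accelerometer, 1 deg/s gyroscope, white Gaussian).

**Sensor model.** The accelerometer is DC-coupled (gravity on VT); the
whole 6-axis signal is rotated by a static pitch tilt (default 5°) before
noise is added. No time-varying orientation drift is modelled: over a 5-m
straight walk trunk-orientation changes are small, and the linear velocity
detrend absorbs their residual.

**Group effects.** At `effect_scale` s, the PD profile has a reaction delay
×(1+0.5s), mean step duration ×(1−0.08s), step count ×(1+0.10s) (shorter,
more numerous steps — keeping gait speed approximately matched, as in
early-to-moderate disease), and roll-axis (AP) angular-velocity amplitude
×(1+0.35s). `effect_scale = 0` makes the groups identical. Cohorts draw
per-subject parameters with multiplicative lognormal jitter (σ = 0.05 on
step timing, 0.15 on reaction delay and amplitudes, ±1 step), keeping all
quantities positive. These magnitudes are design choices on the plausible
scale of early-to-moderate parkinsonian gait; no signal-level population
statistics were available to fit them.

**What the generator does not emulate** — and hence what passing tests do
not establish about real recordings: freezing of gait, tremor, dyskinesia,
asymmetry, turning, time-varying sensor orientation, soft-tissue artifact,
and the full inter-step waveform variability of pathological gait. The
generator's role is to provide signals with *known* events and displacement
on which every detector contract is falsifiable.

## Kinematic reconstruction

Gravity alignment uses the minimal (Rodrigues) rotation taking the mean
standing accelerometer vector onto the VT axis; yaw about the vertical is
unobservable from gravity and left untouched. A standing window must span
≥ 1 s and have gyroscope RMS < 5 deg/s, else the trial is rejected as "not
static". Default anchors: [acoustic − 2 s, acoustic − 0.5 s] and the final
1.5 s of the trial — both inside the protocol's guaranteed 3-s standing
phases.

The zero-velocity update subtracts the straight line through the two
anchor-window mean velocities. It is a projection (idempotent), removes a
constant accelerometer bias exactly, and leaves |mean velocity| < 0.01 m/s
in both standing windows by construction.

## Segmentation

* Thresholds: crossings use ≥ (first sample at or above the threshold), so
  on an analytic ramp sampled at 100 Hz the detected time equals the
  closed-form crossing.
* "Bi-directional 4th-order filter" is realized as `filtfilt` with a
  4th-order Butterworth (zero phase, effective order 8), cutoff 3.5 Hz.
* Peak detection carries a relative prominence floor (10% of the filtered
  signal's range) so that an infinitesimal ripple between the start of
  movement and the first real VT peak is never returned as the first heel
  strike.
* The step template is built from provisional events (filtered-VT peaks,
  ≥ 0.3 s apart) by resampling each inter-event AP segment to the median
  length, averaging, removing mean and linear trend, and scaling to unit
  norm. When six or more provisional events exist, the first and last
  segments (initiation/termination) are excluded: the template should
  represent a steady gait cycle.
* Matching uses a trend-insensitive normalized cross-correlation (each
  window is linearly detrended before scoring), so the match responds to
  the cyclic step shape rather than to the walk's acceleration/deceleration
  trend. Events are correlation maxima above 0.4, at least half a template
  apart, sample-aligned (earliest sample wins at plateaus; no sub-sample
  interpolation — reproducibility is preferred over sub-centisecond
  precision at 100 Hz). On pure noise, isolated chance peaks above the
  floor occur in a minority of traces; a periodic train of ≥ 5 events never
  arises.
* Step indexing: steps 1…m with step i = [eᵢ, eᵢ₊₁] and step m =
  [e_m, t_end] — the last analysed step is truncated at the end of
  movement, and the terminal positioning strike is never analysed. "Middle
  step" is step ⌊(m+1)/2⌋ (ties toward earlier). Whether "second step"
  should instead count from the start of movement is a convention; this
  package counts from the first detected event.
* The VT-peak first-heel-strike estimate and the first matched event are
  independent estimators of the same physical event; when they agree within
  80 ms the earlier is used as the first heel strike so event ordering is
  always consistent.

Measured on the generator at default noise, the matcher recovers every
planted heel strike within ±40 ms with no spurious or missed events (20
trials per group), with a mean absolute stride-duration difference of
~12 ms ≈ 2.4% of a step — the scale expected of trunk-accelerometry event
detection.

## Feature inventory

9 features per phase (duration; AP displacement; AP velocity range; RMS
about the mean — i.e. the within-phase population SD — of acc VT/ML/AP and
gyro VT/ML/AP), for 8 phases, in absolute and relative form, plus 9
across-step means and 2 trial-level parameters: 155 keys per speed
condition, identical for every successful trial. "Relative" is a ratio to
the across-step mean (not a difference); a zero mean yields a flagged NaN,
never a silent zero. The across-step mean of per-step relative values is
exactly 1 — a structural identity used as a test. Across-step means run
over all m steps, not only the named ones. Gait speed is displacement over
duration between start and end of movement. For the self-selected
condition, the two trials' features are averaged per subject before any
statistics.

Gait-variability, symmetry and dynamic-stability measures are deliberately
out of scope: a 5-m episode has too few cycles for them to be valid.

## Statistical protocol

* Normality routing: sample excess kurtosis (bias-corrected) < 0 →
  Shapiro–Wilk; ≥ 0 → Shapiro–Francia (W′ from Blom scores; p-value via
  Royston's 1993 log-normal approximation, validated against R's
  `nortest::sf.test`). Samples of n = 4 always use Shapiro–Wilk, which is
  defined there; the boundary case (kurtosis exactly 0) goes to
  Shapiro–Francia by convention.
* Group tests: Student's pooled-variance t when both groups pass their
  routed normality test at α = 0.05, else Wilcoxon rank-sum (Welch
  available behind a flag). No multiplicity correction — the protocol is
  explorative and reports every p-value.
* Threshold classification scans midpoints of consecutive sorted unique
  values in both directions, maximizing F1 = harmonic mean of sensitivity
  and specificity; ties break toward higher sensitivity, then lower
  threshold. PD is the positive class.
* Preselection: p < 0.05, normal in both groups, then greedy correlation
  pruning — repeatedly find the largest |Pearson r| > 0.7 pair and drop its
  higher-p member — a deterministic survivor set.
* Stepwise LDA: at each step the candidate with the largest F-to-enter
  (partial F from the Wilks' Λ ratio, F = (n−g−p)(Λₚ/Λₚ₊₁ − 1) for g = 2
  groups) joins if p ≤ 0.05; entered variables with F-to-remove p ≥ 0.10
  leave; iteration stops at a fixed point (revisited states terminate the
  loop). Λ along the entry path is non-increasing by construction. The
  final discriminant is a pooled-covariance, equal-prior linear
  discriminant; significance is Bartlett's χ² = −(n − (k+g)/2 − 1)·ln Λ on
  k(g−1) df.
* Cross-validation is stratified, seeded, and re-runs the *entire* stepwise
  selection inside every training fold — the stricter protocol, chosen to
  exclude selection leakage; classical software often re-estimates only the
  coefficients on fixed predictors, which is anti-conservative. Folds in
  which no candidate enters predict the training-majority class, which
  keeps permutation-null accuracy at chance instead of failing the fold.
* Stride agreement between two event streams matches events one-to-one
  within 150 ms (orphans are an error, listed), compares stride durations
  (event i to i+2; a constant offset between streams cancels exactly), and
  reports the mean absolute difference, its percentage of the mean step
  duration, and ICC(2,1) (two-way random, single measure, absolute
  agreement — the specific ICC form is a convention fixed here).

## Calibration (recomputed by `scripts/acceptance.py`)

On null cohorts (no group effect) the comparison pipeline's type-I error at
α = 0.05 stays within [0.03, 0.07] over 2000 draws; at a planted 1-SD shift
with n = 24 vs 14 its power is within 5 points of the closed-form
noncentral-t power (≈ 0.82). Stepwise LDA recovers a planted 1.5-SD
two-predictor signal among 10 noise candidates in ≥ 80% of 100 cohorts, and
under label permutation the 10-fold cross-validated accuracy stays inside
the 95% chance band around the majority-class rate.

## Known limitations

* No gyroscope-updated orientation tracking; large trunk rotations (turns)
  would corrupt the AP integral.
* Single-sensor step events carry no left/right attribution.
* The template matcher assumes at least ~5 quasi-periodic steps; shorter
  or highly irregular walks are rejected with labelled errors rather than
  guessed at.
* The synthetic cohort's effect sizes are design choices; classification
  numbers obtained on it characterize the pipeline's behaviour under known
  conditions, not clinical performance.
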