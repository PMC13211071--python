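# Methods

This note records the models, conventions and design decisions behind
`comfortfuse`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting

Two consumer devices record one wearer per session on independent clocks:
a sports watch (reference clock) collecting ECG-derived RR intervals,
1 Hz record messages (heart rate, wrist skin temperature, pressure,
altitude, GPS speed, heading, a packed 25 Hz wrist accelerometer) and
lap-button comfort labels; and a phone logging ~10 Hz inertial, magnetic,
acoustic and light streams. The modelling unit is a non-overlapping 60 s
window labelled *comfortable* or *uncomfortable* from the lap timeline
(even lap parity = comfortable, session starts comfortable, manual
overrides and inserted boundaries correct missed presses).

## Clock alignment

A three-arm-swing gesture at session start appears as a high-magnitude
spike on both accelerometers. With anchor times `t_G` and `t_P` (elapsed
seconds of the **last** swing on watch and phone), phone times shift by
`t_G − t_P`. The automatic detector looks for peaks ≥ k× the median
magnitude (default k = 5) within the first 20 s and takes the last one;
detections whose qualifying peaks spread over more than 10 s — too long
for a compact gesture — are flagged low-confidence and the session
requires manual anchors. The detector is advisory by design: fixed
thresholds are brittle against sessions that begin with vigorous
activity, so manual anchors always take precedence when supplied.

## Quality gating and windowing

Sessions missing any required file are excluded outright. The phone
stream is scanned for its first inter-sample gap above 5 s (an OS
sensor-throttling data-loss event); the session is truncated at the last
good sample before the gap. The usable span ends at the earlier of the
last phone sample and the last watch record, then loses 90 s of padding
at both ends — start-only for gap-truncated sessions, since the recording
died without the wearer's awareness and there are no end-of-session
behavioural artifacts. The 60 s grid is anchored at the usable-window
start and a trailing partial window is discarded.

A window spanning a lap transition takes the state occupying the majority
of its 60 s; an exact tie takes the state at the window start. Which
side of a transition such windows "should" belong to is genuinely
ambiguous — comfort shifts gradually — so the deterministic
majority/start rule was chosen as the least surprising option, and a
`transition_buffer_s` option excludes any window within a configurable
interval of a boundary for sensitivity analyses.

## HRV features

Artifact rejection keeps RR intervals in **[333, 1500] ms inclusive**
(180 down to 40 bpm). Beat times are reconstructed by anchoring the first
kept beat to the usable-window start and cumulatively summing intervals;
each interval is the gap preceding its beat, so
`diff(beat_time)·1000 == rr[1:]` exactly.

Conventions, pinned by tests:

- SDNN and SDSD are n−1 sample standard deviations; RMSSD divides by the
  number of successive differences; pNN50 uses a strict `> 50 ms`
  comparison; mean HR = 60000 / mean RR.
- Spectral power uses the Lomb–Scargle periodogram evaluated directly on
  the irregular beat times of the mean-centred RR sequence (no
  resampling): grid 0.04–0.40 Hz at 0.004 Hz spacing (≥ 27 points inside
  LF), PSD scaled as 2·P/n, trapezoidal band integrals, LF = [0.04,
  0.15) Hz, HF = [0.15, 0.40] Hz, total = LF + HF, ratio missing when
  HF = 0. VLF is not computed: a 60 s window cannot resolve it. The
  absolute power scale is a convention; band locations and ratios carry
  the signal, and tests assert exactly those (planted 0.10 / 0.25 Hz
  modulations recovered with > 90% band concentration).
- Poincaré: SD1 = √½·SDSD (exactly the dispersion of the lag-1 scatter
  perpendicular to the identity line, verified against a rotated-
  coordinate oracle at 1e−9), SD2 = √(2·SDNN² − SDSD²/2) floored at 0
  against floating-point noise.
- Sample entropy follows the template-counting definition: Chebyshev
  distance, tolerance r = 0.2·SD of the window, ordered pairs i < j with
  self-matches excluded, SampEn = −ln(A/B). Degenerate windows (zero SD,
  A = 0 or B = 0) yield a missing value, never zero. The vectorised
  implementation is tested for exact (1e−12) agreement with an O(n²)
  brute-force pairwise counter.

Windows with fewer than 30 beats after artifact removal produce no HRV
row; the feature matrix keeps such windows with the HRV block missing.

## Context features

Phone windows require ≥ 480 of the nominal 600 samples (data-gap windows
fail this and vanish). All vector statistics operate on Euclidean
magnitudes and are rotation-invariant; jerk uses actual per-sample time
steps rather than the nominal 0.1 s because real streams jitter. Sound is
used in dB as recorded — a consistent relative measure given fixed pocket
deployment, not calibrated SPL. Heart-rate reserve normalises to the
wearer's personal range with defaults HR_max = 203, HR_rest = 60 bpm.
Temperature rate of change is a least-squares slope per minute (robust to
single-sample noise at 1 Hz, unlike a first/last difference). Heading
circular variance (1 − mean resultant length) is computed for the audit
only.

## Feature table and normalisation

The modelled schema is exactly 55 features in nine layers (6 HRV time +
4 HRV frequency + 4 HRV nonlinear + 5 HR + 3 temperature + 3 wrist
kinematic + 22 phone kinematic + 4 acoustic + 4 magnetic). All features
except the four acoustic ones are z-scored within session using the n−1
SD: the model should learn deviations from the wearer's session baseline,
not absolute levels that fingerprint a location. Acoustic features stay
absolute because consistent pocket deployment makes dB levels comparable
across sessions, and z-scoring would erase the quiet-room/noisy-street
distinction. Magnetometer magnitudes stay z-scored: absolute field
strength varies with location, not comfort. Constant z-columns map to 0
(keeping degenerate sessions complete); a single-window session has no
baseline and its z-features go missing.

Candidate features that proxy session identity or reflect deployment
artifacts are excluded through an explicit ledger with reason classes
(`session_proxy`, `deployment_artifact`, `missingness`, `near_constant`,
`quality_indicator`, `context_proxy`); a feature that is neither modelled
nor on the ledger is an error, so the schema cannot drift silently.

## Evaluation

Leave-one-session-out cross-validation with complete-case filtering on
the modelled columns per fold. A held-out session whose usable windows
contain one label is skipped (binary metrics are undefined there) but
trains every other fold. Four classifiers run with library-default
hyperparameters plus class-weight adjustment (uniform priors for naive
Bayes, `class_weight="balanced"` for SVM and random forest,
`scale_pos_weight` for gradient boosting); SMOTE (in-repo k-NN minority
interpolation) is applied to training rows only. The uncomfortable class
is positive; probability ties at 0.5 resolve to uncomfortable because
missed discomfort is the costlier error. AUC uses predicted probabilities
where available and the decision margin otherwise. Fold summaries are
unweighted means ± n−1 SDs over valid folds (SD 0 for a single fold).
Macro and positive-class precision/recall are both emitted; macro is
primary. Seeds fan out from one master seed per (fold, model) through a
seed sequence, making runs bit-reproducible.

## Shapley attributions

Feature and layer importance uses an in-repo Monte-Carlo permutation
Shapley estimator under the marginal-expectation value function: per
sampled permutation, features switch one at a time from a drawn
background row to the explained row, and output deltas accumulate per
feature. The estimator is exactly additive per sample (attributions sum
to f(x) − mean background prediction), gives exactly zero to features the
model never reads, and is verified in tests against exact
subset-enumeration Shapley values on small problems. Layer importance is
the mean of member features' mean |attribution| over five reporting
layers (HRV 14, HR & wrist 11, phone kinematic 22, acoustic 4, magnetic
4), so large layers gain no size advantage. Attribution supports tree
ensembles (random forest, gradient boosting), the models whose
probability surfaces are cheap enough to sample densely.

## The synthetic cohort

The simulator emulates the statistical structure the pipeline assumes,
with defaults set to the pilot's observed contrasts: mean RR 849 vs
778 ms between states (HR 70.7 vs 77.1 bpm), beat SD 30 vs 24 ms (RMSSD
≈ √2·SD ≈ 42 vs 34 ms for near-independent beats), a 0.25 Hz sinusoidal
RR modulation of 15 ms so the HF band is verifiable, wrist temperature
31.9 °C with a +1.4 °C uncomfortable shift, sound 78.0 dB with a −0.6 dB
shift plus an 8 dB between-session spread, and phone accelerometer
magnitude 0.42 vs 0.78 m/s². Slow AR(1) drifts (temperature SD 0.8 °C,
HR SD 4 bpm, timescales of minutes) keep windows within a state
overlapping between classes. Cohorts default to 18 sessions of 25 min
with 8 single-class sessions spread deterministically through the cohort;
the last session starts at 23:26 and runs 40 min to exercise the midnight
guard. The clock offset defaults to 3 s with the gesture at 5 s phone
time; lap presses land on whole seconds as a watch records them.

What the simulator does **not** emulate: cardiovascular dynamics beyond
the two-state Gaussian-plus-tone RR model (no baroreflex, no point-
process beat generation), realistic acoustic scenes (the sound model is a
state-shifted mean with noise — a stand-in, not a claim about any real
environment), posture, and weather. Consequently, passing tests show the
*pipeline* recovers planted structure correctly — offsets, labels, band
power, fold counts, importance rankings — not that free-living comfort is
easy to classify. Under the default conditions every state-linked channel
shifts at each transition, so classifiers reach F1 ≈ 0.98 on the
synthetic cohort; real free-living recordings, where states overlap
heavily and transitions are gradual, sit far lower, and nothing here
should be read as a performance claim about real data.

## Numerical and degenerate-input choices

- Clock alignment is a pure shift: exactly invertible, no drift model.
- RR bound inclusivity: 333 and 1500 ms are kept (removal applies to
  values strictly outside the plausible range).
- A beat at exactly a window's end belongs to the next window (half-open
  intervals throughout).
- sd2's radicand is floored at 0; ratios with zero denominators are
  missing, not infinite.
- Missing values propagate as NaN and are resolved by complete-case
  filtering at model-fit time, never silently zero-filled; GPS speed in
  particular stays missing because its missingness is informative.
- Problem sizes in tests (cohorts of 6–18 sessions, 10–25 min) were
  chosen as the smallest cohorts that exercise every structural rule —
  single-class skipping, the midnight guard, gap truncation — while
  keeping the statistical suites (permutation null, planted-signal
  recovery) well-powered.

## Known limitations

- The exclusion ledger is static; a deployment adding new sensors must
  extend it explicitly (by design, but it is manual).
- The permutation-Shapley estimator samples permutations and backgrounds;
  rankings are stable at the defaults used here, but individual
  per-feature values carry Monte-Carlo noise of order 1/√(permutations).
- Heart-rate reserve uses fixed personal constants; no per-session
  resting-rate estimation is attempted.
- The sync detector assumes the gesture happens within the first 20 s;
  sessions violating the protocol need manual anchors.
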