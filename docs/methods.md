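# Methods

## The system in one paragraph

A participant's (or simulated responder's) EEG is decoded every 0.5 s
into a scalar affect score s ∈ (0, 1) on a continuous sad↔happy axis.
The score drives a rule-based music generator (valence = arousal = s),
and the generated music is the feedback stimulus.  Calibration plays
machine-generated sad/neutral/happy excerpts while recording EEG, then
fits a per-session linear model; the online phase runs rest/action
trials in which the participant tries to steer the music toward an
instructed affective pole.

## Music generation

The generator treats music as five structural parameters controlled by
valence and arousal.  Arousal sets tempo (eighth-note duration
0.3 − 0.15·aro seconds, i.e. 100–200 BPM on the quarter note), rhythmic
density (each of the 8 eighth-note slots per bar sounds independently
with probability aro) and loudness (velocity uniform on the integers
{50, …, round(40·aro + 60)}).  Valence sets pitch register — probability
mass over octaves anchored at C3/C4/C5 (MIDI 48/60/72) — and the
harmonic mode: the seven diatonic rotations of the major scale ordered
from positive to negative perceived valence, Lydian (1) … Locrian (7),
selected by rounding 7 − 6·val half-up and clamping to 1..7.

Harmony is a four-bar I–IV–V–I cycle in the selected mode over C-major
pitch material (the mode's tonic is the corresponding degree of C
major).  The triads are built on scale degrees 1, 4 and 5; when the
degree-4 triad is diminished — only the Lydian mode, whose raised fourth
carries a leading-tone sonority — it is placed after the dominant so the
diminished chord resolves directly into the tonic, giving
F_maj | C_maj | B_dim | F_maj.  All other modes keep plain 1-4-5-1
order (Ionian: C_maj | F_maj | G_maj | C_maj).  Texture: the stochastic
eighth-note stream on piano, the chord root held for the bar on cello
and doubled an octave below on bass — a small chamber-orchestra feel
with one stochastic voice.

Two published forms of the register rule exist in this design space; the
piecewise form that assigns p(C3) = 2·val below val = 0.5 is
non-monotone (low valence would *lose* low-register mass).  The default
here is the monotone variant — p(C3) = 1 − 2·val for val < 0.5,
p(C5) = 2·(val − 0.5) above, remainder on C4 — with the literal variant
available as `pitch_rule="as-printed"`.

Parameter updates quantize to the next eighth-note boundary; mode (and
chord) changes quantize to bar boundaries.  This is what makes gradual
trajectories through affect space sound seamless: no note is retuned or
cut mid-sounding.  Trajectories are zero-order-hold breakpoint lists;
ramps are expressed as dense breakpoints.  The whole stream is a pure
function of (trajectory, seed).

MIDI output is Standard MIDI File format 1 at 960 ticks per quarter,
one track per voice plus a tempo track whose set-tempo events mirror the
note-duration parameter (quarter = 2 × eighth duration).  Round trips
through the bundled reader are exact to well under 1 ms.

## Affect decoding

* **Segmentation.** 4-s windows every 0.5 s (87.5 % overlap).  A window
  belongs to the labeled period containing its *start* sample and may
  extend past the period's end — the same convention the online system
  uses (a score at time t summarizes the preceding 4 s).  A 20-s
  listening period therefore contributes 40 observations; the standard
  calibration schedule yields 80 per class and 120 idle observations.
* **Filtering.** Per segment (no continuous filter state), zero-phase
  (forward–backward) Chebyshev type-I band-pass, order 2, 0.5 dB
  passband ripple, into theta 4–7, alpha 8–13, low beta 14–21, high
  beta 22–29 and gamma 30–47 Hz.  Delta is excluded as artifact-prone.
* **Features.** Natural log of the per-channel variance (ddof = 1) of
  each band-filtered segment: 14 × 5 = 70 features, channel-major.
* **Baseline and scaling.** The mean feature vector over idle windows is
  subtracted from every observation; the two music classes (neutral is
  never fitted) are then standardized feature-wise.  Standardization
  statistics come from the class data only.
* **Classifier.** Closed-form two-class LDA,
  w = (Σ₁ + Σ₂ + λI)⁻¹(μ₂ − μ₁), with the decision threshold at the
  class-mean midpoint, so the discriminant d(f) = wᵀ(f − (μ₁+μ₂)/2) is
  zero exactly between the classes and the sigmoid score
  s = 1/(1 + e^(−α·d)) is 0.5 there for any steepness α.  Happy maps to
  s → 1, sad to s → 0.  α defaults to 2 (system reactivity: how sharply
  the score responds to feature changes).  An uncentered
  `bias_mode="as-printed"` transcription variant exists for comparison.
* **Regularization.** λ defaults to 10⁻² · trace(Σ₁+Σ₂)/70 — scale-free
  Tikhonov shrinkage.  With 70 features from ~80 observations the pooled
  covariance is severely rank-deficient; materially weaker shrinkage
  leaves fold-level refits unstable (cross-validated accuracy on a
  strongly separable synthetic set drops by up to ~15 points purely
  through estimation noise).  A truly singular regularized matrix raises
  rather than silently pseudo-inverting.
* **Online scoring.** One score per 0.5 s from the latest full 4-s
  window, using the stored baseline/standardization; recordings at other
  sampling rates are polyphase-resampled to 128 Hz first.  The model
  serializes losslessly to a single JSON document.

The montage is the 14-channel 10-20 subset AF3 AF4 F7 F8 F3 F4 FC5 FC6
T7 T8 P7 P8 O1 O2 at 128 Hz — a consumer-headset layout.

## Protocol

Calibration presents each of sad (0,0), neutral (0.5,0.5) and happy
(1,1) twice for 20 s in a pseudo-random order with no immediate class
repeats, each excerpt followed by 10 s of silence (idle): 180 s total.
The idle after the final excerpt is included; it is needed for the 120
idle observations and gives the baseline its symmetric coverage.

An online trial is 15 s rest (no music; 30 score updates logged in the
background, the earliest windows reaching back into the previous action
period), task assignment from the mean rest score (< 0.5 → *modulate
toward happy*, ≥ 0.5 → *toward sad*), a 2-s cue gap (appended to, not
inside, the rest period), then 30 s of action with 60 score updates,
each immediately applied to the engine as val = aro = s.  Sessions are
20 or 50 consecutive trials.  For evaluation, each trial also stores the
per-window feature observations of its rest (30) and action (60)
periods, windows labeled by start time; the session runner keeps one
analysis window of lead-in and tail so every window is full length.

## Evaluation statistics

* **Cross-validation.** The two-class calibration data are cut into 1-s
  *non-overlapping* windows (80 observations, 40 per class).  Stratified
  10-fold CV, reshuffled, repeated (default 100×); feature
  standardization and the LDA are re-fit on the training folds of every
  split, so no statistics leak into the test fold.  (The baseline vector
  comes from idle data outside the CV'd observations; as a constant
  shift it cannot affect fold accuracy.)  Reported: overall and
  per-class accuracy and the AUC of the continuous discriminant.  The
  chance threshold is the inverse binomial CDF convention standard in
  BCI decoding: smallest k with P(Bin(n, ½) ≤ k) ≥ 1 − p, as a
  percentage — 58.75 % for n = 80 at p < 0.05.
* **Modulation.** Per task, per-trial rest and action score means are
  averaged into RM and AM; total deviation is task-signed
  (TD_happy = AM − RM, TD_sad = RM − AM) so positive always means
  "moved as instructed"; s̄_diff is the trial-mean of (action − rest).
  One-tailed paired t-tests (right-tailed for → happy, left-tailed for
  → sad) at the marginal threshold p < 0.1.  A task with fewer than two
  trials is reported unavailable — the imbalance that arises when a
  session's resting scores drift to one side.  If all trial differences
  are exactly zero the t statistic is reported as 0 with p = 0.5.
* **Band-power contrast.** One observation per trial: mean action-period
  feature vector minus mean rest-period vector.  Observations are
  scale-normalized within each session (divided by the per-feature SD
  across that session's trials; the mean is *not* removed — centering
  per participant would annihilate the very effect under test), pooled,
  and tested feature-wise against zero with the Bonferroni threshold
  0.05/70.
* **Mood correlations.** Pearson r between the six performance measures
  ({RM, AM, TD} × {happy, sad}) and each mood self-assessment item
  across participant-sessions, with marginal (p < 0.1) and significant
  (p < 0.05) flags; zero-variance columns yield flagged undefined
  entries.
* **Granger causality.** Bivariate, fixed lag order 10 (5 s at the
  0.5-s observation rate), OLS nested-model F-tests, both directions
  between the feedback score and every feature, over the concatenated
  action-period observations (60 per trial).  Bonferroni over all tests
  actually performed (2 × 70 = 140 for the full montage), threshold
  p < 0.01.  Constant or non-finite series are flagged and skipped.
  The implementation agrees with the statsmodels reference to machine
  precision.

## Synthetic data and the simulated responder

`gen_background` draws independent per-channel Gaussian noise shaped to
1/f^exponent in the frequency domain (DC removed), normalized to unit
variance and scaled to a nominal 10 µV SD — the canonical EEG spectral
shape without any physiology.  Calibration recordings add band-limited
oscillatory components (band-filtered white noise, *not* pure sinusoids,
so log-variance features stay realistically dispersed) on designated
channels during music periods, with class-specific amplitudes.  The
default calibration effect is alpha (8–13 Hz) on the posterior channels
P7/P8/O1/O2 with the sad class at 3× the happy amplitude (low-arousal
states carry more alpha); the responder instead couples through gamma
(30–47 Hz) on FC5/FC6 with happy = more gamma, echoing the band/site
most consistently implicated in felt affect.  A 4-s background tail
after the 180-s schedule keeps every start-labeled window full length.

The responder is a streaming EEG source with an internal affect state
s\* ∈ [0, 1]: first-order drift toward the task target during action
periods (rate 0.5 s⁻¹), relaxation toward a personal resting set-point
otherwise (rate 0.3 s⁻¹), plus small Ornstein–Uhlenbeck-like
fluctuations (SD 0.08 √s) — people neither track perfectly nor sit
still.  The state is expressed as the amplitude of the coupled-band
component via a monotone gain map that is *linear in log band power*
(geometric interpolation of total in-band variance between the sad- and
happy-level amplitudes): state 0.5 then lands at the feature-space
midpoint of the calibrated classes, which is what the decoder's
midpoint-centered discriminant measures.  The resting set-point defaults
to 0.45, slightly on the low-arousal side, which makes *modulate toward
happy* the more frequent task — the distribution observed in practice.
`make_responder_setup` calibrates a model on data whose planted effect
matches the responder's coupling (same band, channels and amplitude
scale), the precondition for the loop to close.

What the generators deliberately do **not** emulate: volume conduction
and channel correlation, eye-blink/EMG artifacts, non-stationary drifts
(electrode drying, vigilance), individual spectral peaks, or any real
coupling between heard music and brain state — the responder listens to
the *task*, not to the audio.  Passing tests therefore demonstrate that
the pipeline's machinery is correct and that the closed loop behaves as
designed when its assumptions hold; they say nothing about decoding
accuracy on real human EEG.

## Numerical choices and edge cases

* Round-half-up for the discrete mode index and the velocity upper
  bound; velocity is a discrete uniform inclusive of both endpoints.
* Natural logarithms throughout; variance with ddof = 1.
* The sigmoid output is clamped to [10⁻¹², 1 − 10⁻¹²]: the score is an
  open-interval control signal and float saturation would otherwise
  produce exact 0/1.
* Filters are designed once per (band, fs, order, ripple) and cached;
  filtering is vectorized across channels per segment.
* A flat (zero-variance) channel raises — log band power is undefined
  and it signals a dead electrode, not a condition to paper over.
* Windows that would run past the end of a recording are dropped with a
  warning; a labeled period shorter than the step contributes zero
  windows, with a warning.
* Mid-bar trajectory changes affect tempo/density/loudness at the next
  slot; the bar's chord is fixed at the bar start.
* MIDI note-off collisions are resolved FIFO per pitch; a note-on with
  velocity 0 counts as note-off.

## Problem sizes used in the test battery

The statistical acceptance checks run at deliberately compact sizes:
null-effect cross-validation over 20 generator seeds at 10 CV repeats;
one strong-effect recording at 10 repeats; one 20-trial closed-loop
session; band-power type-I calibration on 20 feature-level null
sessions of 20 trials; Granger recovery on 600-sample planted pairs.
These sizes give the binomial/t/F statistics comfortable resolution for
the claims tested while keeping the whole battery fast enough to run on
every commit.

## Known limitations

* The decoder fits exactly two classes; neutral excerpts serve only as
  spacers during calibration.
* No artifact handling of any kind, by design parity with the modeled
  system.
* The Granger analysis is pairwise-bivariate at a fixed lag order; no
  conditional/multivariate variant, no lag-order selection, no
  stationarity testing beyond a constant-series guard.
* The score↔feature causality found in simulation partly reflects the
  mechanical overlap between scoring windows and feature windows; on
  real data the same caveat applies to any such analysis at this
  observation rate.
* Session simulation is sample-synchronous (no wall-clock pacing, no
  dropped blocks); hardware acquisition is out of scope.
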