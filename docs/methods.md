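# Methods

`omgpipe` implements a complete, testable analysis pipeline for
optomyography (OMG) smart-glasses recordings of posed facial expressions:
a synthetic-data generator standing in for the (non-public) study data, the
two preprocessing chains, the paired statistical comparisons, and the
windowed-feature expression recognizer with leave-one-subject-out (LOSO)
evaluation.  This note records the model, its parameters, and the design
choices made where the procedure was genuinely open.

## Signals and protocol

Six 3-axis optical sensors report skin displacement in millimetres at 50 Hz
— left/right cheek (zygomaticus major), left/right brow
(frontalis/corrugator region) and left/right temple — giving 18 streams
named `{site}_{axis}`.  A session consists of three tasks, each presenting
four expressions (smile, frown, eyebrow raise, squeezed eyes) three times
per condition:

* **Task A** — low/high intensity x 1 s/3 s duration grid, head still,
  glasses at the medium position;
* **Task B** — high-intensity 3 s expressions with head movement in four
  directions;
* **Task C** — high-intensity 1 s/3 s expressions with the glasses low,
  medium and high on the nasal bridge.

Participants rest (neutral) between repetitions.  The rest lengths are
task-specific (3 s, 4.3 s, 5.2 s): the statistics chain removes one linear
trend per stream over the *whole* session, so any whole-session trend in
expected activation level would tilt the recovered baseline of one task
against another and masquerade as a condition effect.  Given the 3 s Task A
rest, the B/C rests are set where that whole-session activation trend
vanishes, which makes the designed between-task null comparisons (e.g. head
movement) hold by construction.  The expression order inside each condition
group is shuffled per participant for the same reason: no expression is
pinned to a fixed offset in the session.

## Generative model

Each expression event contributes a trapezoidal activation envelope
(raised-cosine onset/offset of 0.25 s, unit plateau).  The plateau height of
site *s* for expression *e* is

    amplitude(e, s) = C[e, s] * scale_p(s) * gain_p(region(s), e)
                      * vigour(block) * effort(trial)
                      * attenuation_p^[low intensity] * posgain(e, s, position)

with, per participant *p*:

* `C` — the coupling matrix (mm), calibrated as described below;
* `scale_p(s)` — per-site lognormal amplitude scale (sigma 0.15, median 1);
* `gain_p(region, e)` — per-(region, expression) lognormal gain
  (sigma 0.15): people differ in how strongly each muscle engages;
* `vigour` and `effort` — symmetric multiplicative jitters
  `1 + N(0, 0.15)` per condition block and `1 + N(0, 0.2)` per repetition.
  A symmetric law is deliberate: condition cells pool different numbers of
  trials (3 for the still cell, 12 for the moving cell), and the median of
  an n-trial mean of a *skewed* jitter depends on n, which a signed-rank
  test across participants would detect as a spurious shift;
* `attenuation_p` — low-intensity factor, `N(0.5, 0.04)` clipped to
  [0.35, 0.65] (low-intensity movements are roughly half scale);
* `posgain` — glasses-position gains.  Brow-site activation is reduced when
  the frame rides low or medium (0.9 for eyebrow raise/frown, 0.88/0.97 for
  squeezed eyes) and amplified when high (1.2, 1.15); the smile is
  unaffected; squeezed eyes also modulates the cheek sites
  (0.89/0.99/1.12).  Each expression's gains average 1 across positions so
  Task C does not shift the session mean.

The site activation is projected onto a fixed per-site unit direction with
a small per-participant perturbation (the downstream magnitude only needs a
consistent decomposition), then superimposed on: a constant per-stream
offset (±0.4 mm), linear drift (±0.003 mm/s), a slow non-linear baseline
wander (three random-phase sinusoids per stream, periods 2–10 min,
amplitude scale 0.5 mm — real sensor drift is not perfectly linear, and the
wander gives each participant an independent baseline history), and white
Gaussian noise (sigma 0.12 mm per axis sample).

Head movement adds a zero-mean sinusoid (integer number of cycles over the
event, below 1 Hz for the 3 s movement events, amplitude 0.35 mm) projected
on a direction-specific axis pattern and added to all streams.  Because it
integrates to zero it cannot shift an event's mean displacement: the
head-movement null is designed in, not emergent.

### Coupling calibration

The published quantities are combined (left+right) event-mean movements,
medians across 27 participants: at high intensity 12.14/12.70/4.70/5.17 mm
on the cheek and 16.16/14.14/11.51/4.00 mm on the brow for
smile/squeezed-eyes/eyebrow-raise/frown (cheek) and
raise/squeezed/frown/smile (brow).  The map from plateau coupling to that
statistic is not a simple duty-cycle scaling: whole-session detrending both
offsets the magnitude trace and folds it where activation falls below the
baseline.  `calibrate_coupling` therefore inverts the map by fixed-point
iteration against a noiseless forward simulation of the exact chain
(envelope -> detrend -> magnitude -> bilateral sum -> rolling median), to
0.01 mm.  For a noiseless site whose axes are proportional to one unit
vector this forward model collapses to `2*|detrend(A)|` of the scalar
activation, so the calibration costs a few hundred milliseconds.  Temple
couplings (no published values) are fixed small constants (0.5–1.4 mm).

## Preprocessing

* **Statistics chain** (per region): per-stream linear detrend over the
  whole recording -> per-sensor vector magnitude sqrt(x²+y²+z²) ->
  left+right sum -> centered rolling median, 15 samples, shrinking windows
  at the edges (length preserved).  The listed order is followed as stated:
  detrending acts on raw per-axis streams *before* the magnitude.
* **ML chain** (per stream): zero-phase (forward-backward) 4th-order
  Butterworth low-pass, then linear detrend.  The filter is otherwise
  unspecified in the source procedure; 10 Hz is used because voluntary
  facial movement energy sits well below it at 50 Hz sampling, and zero
  phase preserves event timing for labelling.  Cutoff and order are
  configurable (`FilterSpec`).  An optional 30 mm out-of-range mask (the
  sensors' specified working range) is exposed and off by default.

## Statistics

Per participant and condition level, the movement statistic is the mean of
the processed trace over each event interval, averaged over that level's
events.  Levels are compared with the two-sided Wilcoxon signed-rank test:
zero differences discarded, exact null distribution for n <= 25 non-zero
differences without ties, otherwise the normal approximation with tie and
continuity corrections (identical samples give p = 1 with a warning).
Bonferroni families follow the comparison sets drawn per analysis: m = 6
for the all-pairs expression analysis (per region), m = 4 for head movement
(per region, one test per expression), m = 3 for glasses position (per
expression per region).  Significance is annotated on the conventional
descending ladder (`****` for p < 1e-4, `***` < 1e-3, `**` < 1e-2,
`*` < 0.05, `ns` otherwise).  The head-movement comparison contrasts the
controlled task's high-intensity 3 s events (still) with the
head-movement task's events (moving).

## Features and recognition

The 18 ML-preprocessed streams are segmented into contiguous 0.1 s windows
(5 samples, stride = window, trailing remainder dropped) and summarised by
nine statistics each — mean, standard deviation, min, max, range,
interquartile range, kurtosis, skewness, RMS — 162 features per window.
Conventions that matter at 5 samples: population (bias-uncorrected)
moments, excess kurtosis, skewness/kurtosis defined as 0 for zero-variance
windows, and linear-interpolation quantiles for the IQR.  Windows take the
majority per-sample label, ties broken in favour of the non-neutral class;
neutral windows inherit the enclosing block's condition metadata.  Features
are standardized per participant over all of that participant's windows,
mirroring the stated procedure; a train-fold-only alternative would avoid
the (mild) transductive leakage but is not the default, for fidelity.

The recognizer is a Random Forest: 40 trees, sqrt(d) features per split,
unlimited depth, each tree fit on a 15% bootstrap subsample.  At this
cohort's class separability the accuracy plateaus well below 40 trees, and
the modest ensemble keeps a full 27-fold LOSO run cheap on a single core.
Per fold, the neutral class of the *training* partition is undersampled
without replacement to the rounded mean of the four expression-class counts;
the held-out participant is untouched.  Condition-sliced reports
(intensity, movement, glasses position) re-score the predictions of the one
model per fold on the matching test windows; no retraining per condition.
Metrics are computed in full precision and rounded to two decimals only for
display.

## What the synthetic data does and does not show

The generator reproduces the study's *structure*: displacement scales and
their orderings across expressions and regions, the intensity ratio, the
designed nulls (head movement, close expression pairs), the position
effects on the brow, inter-participant and trial-to-trial variability, and
a realistic session length (~11,200 windows per participant).  It does not
model optical sensor physics, cross-talk between muscles, involuntary
micro-expressions, or individual facial anatomy; recognition accuracy on
synthetic cohorts is therefore an upper bound on what identical code would
achieve on real recordings, and passing tests validate the pipeline's
correctness and the direction/order of effects, not field performance.

## Numerical choices and degenerate inputs

Exact windows at 50 Hz (all protocol durations are multiples of 0.02 s);
half-open sample intervals everywhere; detrend of a constant-or-line stream
returns zeros to ~1e-12; a constant feature within a participant
standardizes to zeros with a warning; an all-zero paired difference vector
yields p = 1 with a warning rather than an error; event rendering requires
>= 0.5 s.  Cohort generation derives one child RNG per participant from
`[seed, index]`, so cohorts are bit-reproducible and participants are
independent.

## Problem sizes used in the shipped checks

The acceptance run uses the full default cohort (27 participants, complete
three-task protocol, ~302,000 windows) for the LOSO evaluation and the
statistical analyses; replicate studies of the designed effects use 20
seeded cohorts; the permutation-null check uses a 6-participant,
controlled-task-only cohort, which is ample to distinguish chance (0.2)
from structure.  The type-I control study uses 15-participant cohorts of
the controlled task under a flattened (uniform-coupling, identity-gain)
generator.
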