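# Methods

This note documents the models, conventions and numerical choices behind
`equigait`: what the synthetic generator emulates, how every stride
variable is defined, how the classifiers and the cross-validation
protocol are configured, and what the test suite does and does not
demonstrate about real sensor data.

## 1. Synthetic gait generator

### Gait presets

Each of the eight gait classes is parameterized by a `GaitPreset`:
per-limb phase offsets (hoof-on as a fraction of the stride), a
duty-factor mean/SD (percent of stride), a stride-duration mean/SD
(seconds) and a phase-jitter SD.  Duty-factor and stride-duration
moments are population descriptive statistics for 7576 strides of 120
horses of four breeds; phase offsets encode the canonical footfall
orderings:

| gait    | pattern | offsets (LH, LF, RH, RF) | duty % | stride s |
|---------|---------|--------------------------|--------|----------|
| walk    | lateral-sequence 4-beat | 0, .25, .5, .75 | 60.60 ± 1.85 | 1.07 ± 0.17 |
| trot    | 2-beat, diagonal pairs  | 0, .5, .5, 0    | 44.20 ± 4.76 | 0.63 ± 0.12 |
| lcanter | 3-beat, RH trailing     | .3, .45, 0, .3  | 39.10 ± 3.58 | 0.50 ± 0.05 |
| rcanter | 3-beat, LH trailing     | 0, .3, .3, .45  | 40.00 ± 3.28 | 0.49 ± 0.04 |
| tölt    | lateral-sequence 4-beat | 0, .25, .5, .75 | 36.10 ± 2.63 | 0.42 ± 0.04 |
| pace    | 2-beat, lateral pairs   | 0, 0, .5, .5    | 44.20 ± 3.78 | 0.54 ± 0.04 |
| paso    | lateral-sequence 4-beat | 0, .25, .5, .75 | 53.70 ± 2.49 | 0.39 ± 0.03 |
| trocha  | dissociated trot (δ = 0.08) | 0, .5+δ, .5, δ | 51.00 ± 3.34 | 0.39 ± 0.04 |

Notes on values that required a decision:

* **Walk stride duration.**  The published walk row is internally
  inconsistent: the printed 1.80 s disagrees with the printed stride
  frequency (0.95 Hz ⇒ ~1.05 s) and with stance 0.65 s at duty 60.6 %
  (⇒ ~1.07 s); all other gaits satisfy both identities.  The default
  walk preset uses the derived 1.07 s; `builtin_presets(
  walk_printed_duration=True)` restores the printed value.
* **Canter offsets** are not tabulated anywhere; the presets encode the
  standard transverse three-beat order (trailing hind → synchronous
  diagonal pair → leading fore) with the leads as mirror images, at
  0 / 0.3 / 0.45.  They are ordinary preset fields and can be changed.
* **Trocha** is modeled as a trot whose diagonal partners are dissociated
  by δ = 0.08 stride, with a raised jitter SD (0.025 vs 0.01 for the
  other gaits) reflecting its notoriously irregular timing.

### Timelines

`generate_timeline` draws each stride duration from a Normal truncated
below at 0.2 s (mean × the horse's multiplier), one duty-factor value per
stride shared by all four limbs (so stance and stride durations co-vary)
plus small per-limb noise (SD = 0.1 × the duty SD, hence exactly zero for
ideal presets), and places each hoof-on at its phase offset plus Gaussian
jitter.  Hoof-off follows at `duty/100 × stride duration`.  All
randomness flows through one root seed; per-horse and per-trial child
generators are derived by hashing the identifiers, so adding a horse to a
cohort does not reshuffle the others.

### Cohorts emulate the study conditions

`CohortConfig` defaults describe a 33-horse cohort (10 warmblood, 10
Icelandic, 5 Franches-Montagnes, 8 Colombian criollo) with the breed →
gait availability of the reference data set (tölt/pace only in
Icelandics, paso/trocha only in Colombians), per-gait stride totals
proportional to the published stride counts (walk and trot dominate,
pace is rarest), and three sources of speed/conformation variation:

* a **breed multiplier** on stride duration (warmblood 1.08, Icelandic
  0.97, Franches-Montagnes 1.02, Colombian criollo 0.82) reproducing the
  breed clustering of stride durations; the low Colombian value places
  that breed's trot in the high-frequency range adjacent to trocha;
* a **per-horse multiplier** (SD 0.06 around the breed base), drawn once
  per horse;
* a **per-trial lognormal speed factor** (σ = 0.15): locomotion speed was
  not controlled in the reference recordings, and this is what makes
  absolute temporal variables (stride duration, stance duration,
  frequency) weak features relative to the dimensionless ones, as
  observed.  The within-trial stride SD is shrunk to 0.4 × the
  population SD so pooled per-gait spreads still approximate the
  published statistics.

**Trocha–trot continuum.**  Field descriptions place trocha on a spectrum
with the trot ("a trot with a high stride frequency"; often "less clean"
footfall timing, possibly mislabeled).  Each trocha trial draws a
cleanness factor c ~ U(0.4, 1) and interpolates its generative parameters
between the trot preset (c = 0) and the trocha preset (c = 1).  This is
what gives the synthetic cohort the characteristic trot↔trocha confusion;
set `trocha_min_cleanness = 1.0` for ideal trocha only.

### Signal model

The raw-signal path is exercised by an intentionally simple synthesis —
it is plumbing, not a biomechanical simulation.  Limb channels carry an
exponentially decaying transient (τ = 30 ms) at each hoof-on with
amplitude ∝ 1/stance-duration (so faster gaits have larger impact peaks,
matching the observed magnitude differences between e.g. trot and walk),
plus a swing-phase oscillation on the gyroscope axes.  Upper-body
channels (poll, withers, pelvis) receive fore/hind-weighted attenuated
sums of the limb transients and a vertical harmonic locked to stride
phase — two beats per stride for gaits with a synchronous limb pair,
one otherwise — plus Gaussian noise (default SD 0.3 in signal units,
roughly a tenth of a typical impact peak).  Consequences worth knowing:
the signals are perfectly periodic apart from jitter and noise, contain
no soft-tissue artifacts, drift, sensor saturation or gait transitions,
and single-gait blocks are guaranteed.  High classification accuracies
on these signals therefore demonstrate that the pipeline is correct and
that the models can exploit gait-dependent structure — not that the same
accuracy would be reached on real recordings.

## 2. Stride features

A stride runs from one reference-limb hoof-on to the next; the reference
limb defaults to the left hind (hind-centric, Hildebrand's convention)
and is configurable.  Windows missing a limb onset are dropped, not
imputed.

Numerical conventions, each the result of an explicit decision:

* **Onset anchoring.**  Each limb is anchored to its first onset at or
  after the window start, with a slack of 10 % of the stride past the
  window end.  A limb synchronous with the reference (the trot's
  diagonal partner) jitters across the window edge; requiring the onset
  strictly inside the window discards ~25 % of such strides *and* the
  discarded windows are systematically shorter, which biased recovered
  duty factors by ~4 SE at n = 10⁴.  With slack anchoring all interior
  windows are complete and recovery is unbiased.
* **Duty factor** divides each limb's (unclipped) stance by the
  reference stride cycle that stance belongs to — the current window, or
  the next reference cycle when the onset was borrowed from past the
  edge.  Dividing by the limb's own onset-to-onset cycle instead
  re-introduces a Jensen-type bias for mid-phase limbs when stride
  durations vary.  Both the four-limb mean (`duty_factor`, the tabulated
  convention) and the hind-limb-only value (`duty_factor_hind`,
  Hildebrand's convention) are exported; the four-limb mean is the
  default everywhere.
* **Advanced placements** are per-pair circular differences mapped to
  (−50, 50] and combined across the left/right pairs by a *circular*
  mean.  An arithmetic mean collapses to ~0 whenever the two trot pairs
  jitter onto opposite sides of the ±50 wrap point (2 % apart on the
  stride circle, 98 apart numerically).  A 10⁻⁹ tolerance keeps an
  exactly-half-stride difference from flipping to −50 through
  floating-point noise.  Positive sign = fore contact follows hind.
* **Support profile** is an exact event sweep over stance boundaries
  clipped to the window; segment lengths sum to the stride duration to
  machine precision, so the five support-category percentages sum to
  100 exactly.  `median_limbs` is the time-weighted (lower) median of
  the profile.  A dense-grid oracle (10⁴ samples/stride) agrees with the
  sweep to within one grid step on randomized timelines.
* **Limb-pair overlaps** are measured on the stride circle (intervals
  reduced mod the stride duration), so a stance phase split by the
  window boundary is never undercounted.
* Onsets within 1 ms are *displayed* as simultaneous in footfall-order
  summaries but never merged in arithmetic.

The feature table has 21 fixed-order columns: the 20 tabulated variables
plus `duty_factor_hind`.

## 3. Classifiers

Feature models are scikit-learn estimators behind a uniform surface:
LDA; QDA (covariance shrinkage 10⁻³, since several features are constant
within a class); decision tree; random forest (100 trees); SVM (RBF
kernel, one-vs-one); and a one-hidden-layer network (40 units, Adam,
fixed 200-epoch budget).  Discriminant/margin/neural models receive
per-column z-scoring with training-fold statistics; trees and forests
consume raw features.  The FC model deliberately does *not* use
accuracy-plateau early stopping: with well-separated gaits a small
validation slice scores 1.0 at the first epoch and best-weight
restoration would freeze the underfit initial model.

The sequence model is a stacked GRU written in numpy (no deep-learning
framework is used): temporal mean-pooling of the input to ≤ 25 steps,
1–2 recurrent layers of width 64 by default (width is a config knob; the
full-scale reference used width 500, which is permitted but not required
at desk scale), optional bidirectionality (separate parameters per
direction, ≈ 2× recurrent parameter count), mean-pooled states into a
softmax readout.  Training: Adam (lr 10⁻²), batch 32, cross-entropy,
early stopping on a 10 % validation split (patience 8), fixed epoch
budget (default 40; 30 in the evaluation grids).  All gradients are
derived by hand and checked against finite differences in the test
suite.  Signals are min–max normalized to [0, 1] per channel and per
recording before windowing (the normalization scope in the reference is
unstated; training-statistics application with clipping is available as
the alternative); windows are consecutive and non-overlapping (1, 2 or
3 s), the trailing remainder dropped.

Class imbalance is handled by duplicating minority-class training rows
to the majority count, on training folds only.

## 4. Evaluation protocol

`grouped_kfold` partitions *horses* (never strides) into k = 5 folds,
greedily balancing stride counts because breeds contribute very
different totals; an optional held-out test fraction (default 0.2 where
used) is removed before folding.  `cross_validate` asserts on every fold
that no horse appears on both sides; a leaky plan raises.  Accuracy is
micro-averaged (confusion-matrix trace over total); the "five runs" of a
grid cell are the five folds.  The experiment grid runs (model kind ×
feature subset) and (sensor subset) cells under one shared plan and
supports gait-exclusion reruns.

Feature-subset comparisons report the best model kind per subset,
mirroring how the reference comparisons are framed (the best all-features
model was an FC network, the best two-variable model a decision tree);
per-kind orderings are not uniform because an MLP handles the circularly
wrapped LAP worse than axis-aligned trees do.

## 5. Problem sizes

Default problem sizes were chosen so the whole suite runs comfortably on
one CPU: the standard cohort is 2000 strides across 33 horses (feature
grids: 6 kinds × 3 subsets × 5 folds in ~15 s); parameter recovery uses
10⁴ strides per gait; the raw-signal experiments use an 11-horse,
8-gait cohort of ~300 one-second windows with the width-64 GRU
(three sensor subsets × 5 folds in ~2–3 min).

## 6. Known limitations

* The signal model's simplicity (section 1) bounds what raw-signal
  accuracies mean; transfer to real IMU data is untested and out of
  scope (no recordings are deposited).
* Trot/pace LAP is inherently bimodal at ±50 — a property of circular
  statistics, not a bug; linear models suffer from it by design.
* The canter leads are indistinguishable in (duty, LAP) alone; any
  two-variable model caps well below 100 % on cohorts containing both.
* Hoof-event detection from raw signals, spatial variables (speed, step
  length), lameness/asymmetry modeling and gait transitions within a
  block are not modeled.
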