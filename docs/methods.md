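# Methods

## Problem and scope

`gaitspeed` classifies short windows of body-worn tri-axial accelerometry
into three walking-speed categories — slow (≤ 4 km/h), moderate
(4.1–5.4 km/h), brisk (≥ 5.5 km/h) — plus jogging (> 6.4 km/h), from a
thigh sensor, a low-back sensor, or both.  It implements the whole chain
needed to study that task under a semi-structured protocol: a synthetic
signal generator standing in for the real cohort, recording I/O and
heel-drop synchronization, window segmentation and feature extraction,
participant-grouped gradient-boosted-tree training with
leave-one-subject-out (LOSO) cross-validation, and metric reporting.

The package assumes the input periods are already known to be walking or
jogging (it is a speed classifier, not an activity-type detector), and it
only treats level locomotion: uphill/downhill and stair gait, surface and
footwear effects, and pathological gait are out of scope.

## Synthetic protocol generator

The generator emulates a 24-participant semi-structured protocol: five
consecutive bouts (default 300 s each) of slow, moderate and brisk walking,
jogging, and a slow→brisk→slow speed ramp, separated by 2-s standing gaps
and bracketed by 5-s pads containing three heel-drop impulses each.  The
labelled (non-"other") span is exactly 25 min per participant; sampling is
50 Hz and all amplitudes stay inside the sensors' ±8 g range.

Per site the signal is

```
a(t) = g_proj + Σ_{k=1..3} (A(v)·w_axis/k)·sin(k·φ(t) + φ0) + impacts(t) + ε(t)
```

* `g_proj`: static gravity projection for the site's tilt angle (per-axis
  constant of unit magnitude).
* `φ(t) = 2π ∫ f_step dt` with step frequency
  `f_step = (c0 + c1·v)/60` Hz; cadence is linear in speed with defaults
  `c0 = 85` steps/min and `c1 = 10` steps/min per km/h.
* `A(v) = 0.06·v · amplitude_gain · site_gain` g: harmonic amplitude grows
  linearly with speed and vanishes at standstill; `site_gain` is 1.0 for
  the thigh and 0.45 for the back, so thigh dynamic range always exceeds
  back dynamic range during gait.
* `impacts(t)`: while jogging only, each step adds a 60-ms half-sine
  transient of peak `(1.8 + 0.15·v)·amplitude_gain` g (back scaled by
  0.7) on the longitudinal axis.  Because the impact peak and the walking
  harmonics both scale with `amplitude_gain`, jogging peak magnitude
  exceeds brisk-walking peak magnitude for every cohort profile.
* `ε(t)`: white Gaussian noise, default SD 0.05 g per axis — enough to make
  the task non-trivial while keeping classes separable.

Constant bouts draw a per-participant target speed from a truncated normal
centred in the bout's target interval (slow 2.3–3.7, moderate 4.4–5.3,
brisk 5.7–6.8, jogging 7.1–9.7 km/h — the observed per-condition ranges)
and add a slow sinusoidal wander of 10 % of the interval width, clipped to
the interval; the realized mean speed therefore always stays inside the
target interval and never crosses a class boundary.  The ramp bout is
piecewise linear (3.1 → 6.1 → 3.1 km/h) and crosses the class cut-offs,
producing the label sequence slow, moderate, brisk, moderate, slow.

Cohort heterogeneity: sex (14:10 female:male), age, height and mass are
truncated normals bracketing the emulated study sample by sex; cadence
intercept (SD 4 steps/min), cadence slope (SD 0.6), movement vigour
`amplitude_gain` (SD 0.15, range 0.7–1.4), and sensor tilts vary across
participants so that subjects differ in both spectral and amplitude
feature space — this is what makes LOSO generalization non-trivial.

What the generator does *not* emulate: within-bout gait variability beyond
the smooth speed wander, turning, asymmetry, sensor repositioning, soft
tissue artefact, and the long-tailed noise of real accelerometers.
Passing tests therefore demonstrate that the pipeline recovers structure
it is designed to recover; they do not certify accuracy on real
recordings, whose headline numbers require the real cohort.

### Speed-to-class convention

The printed category bounds leave (4.0, 4.1) and (5.4, 5.5) km/h
undefined; the package closes the gaps at their midpoints (slow: v ≤ 4.05;
moderate: 4.05 < v ≤ 5.45; brisk: v > 5.45), configurable via arguments to
`speed_to_class`.  A continuous ramp trace then maps every speed to a
class.  Jogging is decided by locomotion mode, not speed.

### Heart-rate utility

`compute_percent_hrmax(age, hr)` returns `100·hr/(208 − 0.7·age)` using
the Tanaka estimate of maximal heart rate.  Heart-rate and perceived
exertion signals are not simulated; they play no role in classification.

## Signal I/O and synchronization

Recordings travel as plain CSV (`# participant= / # site= / # fs=` header
lines, then `timestamp,ax,ay,az` at 6 decimal places); any converter from
vendor binary formats can emit this dialect.  Resampling is linear
interpolation onto a uniform grid spanning the original time range —
exactly testable and idempotent; no per-subject amplitude standardization
is applied, because feature semantics require absolute g units.
`clip_to_range` emulates the ±8 g sensor range and logs the number of
saturated samples.

Heel-drop detection high-pass filters the vector magnitude (4th-order
Butterworth at 5 Hz, zero-phase) and takes the first and last
`expected_per_marker` peaks above 1 g (0.4 s minimum separation) as the
start/end marker groups; jogging impacts between the markers are ignored
by position.  Synchronization estimates an affine clock map
`t_a = α·t_b + β` (offset + linear drift) from the paired marker-group
centroids, then interpolates the second stream and maps the label
intervals onto the reference clock.  With the default 4 g / 100 ms
impulses and 0.05 g noise, injected offsets of ±2 s and drifts of 0.1 %
are recovered with sub-sample residuals.

## Windows and features

Windows are non-overlapping, default lengths 1, 3 and 5 s; trailing
partial windows are dropped and windows are aligned across sensors.  A
window's label is the strict-majority class of its samples; ties and
"other"-majority windows (transition gaps, marker pads) are discarded.

The gravity/body split is a 4th-order zero-phase Butterworth low-pass at
1 Hz (gravity) with the body component as residual.  Spectral statistics
use a single-window FFT with a periodic Hann taper (bin width 1/length
Hz); the DC bin is excluded, and numerically silent windows yield zeros
(including a zero, i.e. minimal, spectral entropy).  Statistics use
population (ddof = 0) moments; skewness/kurtosis of a constant window are
defined as 0; the zero-crossing rate counts sign changes of the demeaned
signal per sample step; Pearson correlations involving a zero-variance
channel are defined as 0.

The catalogue is fixed so the dual set-up emits exactly 161 features:
78 per sensor (12 time-domain stats × 4 channels, 3 per-axis gravity
means, 3 axis-pair correlations, 8 spectral stats × 3 axes) plus 5
cross-sensor features (magnitude correlation, body-magnitude correlation,
body-magnitude RMS ratio, body-magnitude dominant-frequency difference,
magnitude range ratio).  Every entry has a brute-force oracle in the test
suite; the catalogue is exported as JSON alongside extracted matrices.

## Classifier and cross-validation

The learner is XGBoost (`tree_method="hist"`, single-threaded, seeded —
bit-reproducible).  Hyperparameters come from a participant-grouped
six-fold grid search (default grid: depth {3, 6}, learning rate
{0.1, 0.3}, boosting rounds {100, 300}, subsample 0.8, column subsample
0.8); folds are grouped because window-level folds leak subject identity
and inflate validation scores.  Ties are broken toward the smaller
ensemble, then the lower learning rate, then grid order.  Final evaluation
is leave-one-subject-out: one fold per participant, the held-out subject
contributing no training windows.  Class probabilities follow the fixed
class order (slow, moderate, brisk, jogging), which also serves as the
arg-max tie-break.  No class weighting is applied; the protocol balances
bout durations by design.

## Metrics

Per class, one-vs-rest: sensitivity TP/(TP+FN), specificity TN/(TN+FP),
precision TP/(TP+FP), F1 = 2·prec·sens/(prec+sens); overall accuracy is
the proportion of correctly classified windows.  Undefined ratios (zero
denominators, e.g. a class absent from a subject's windows) are reported
as `None`, never silently replaced by 0; a single subject's SD is reported
as not-available.  Confusion matrices carry labelled classes in rows and
predictions in columns, with row-percent normalization (empty rows are
flagged, not divided).  Reports give both pooled all-window metrics and
per-subject metrics aggregated as mean / sample SD / min / max — the
per-subject mean is the headline figure — and per-class values alongside a
macro average.

## Problem sizes and numerical choices

The test suite exercises the full protocol shape with 30–60 s bouts and
4–8 participants; the acceptance script runs the complete default
experiment cell (24 participants, 25 labelled minutes each, dual set-up,
5-s windows, fixed default hyperparameters) plus a 20-draw
synchronization-recovery experiment.  Determinism is enforced end to end:
integer seeds feed `numpy.random.default_rng`, per-bout child generators
are derived from the participant seed, CSVs are written with fixed float
formatting, and rerunning a pipeline configuration reproduces
byte-identical artefacts.

## Known limitations

* The waveform model is phenomenological; feature values are not expected
  to match real gait, only to order and separate classes the same way.
* Adjacent walking speeds overlap across subjects by construction
  (cadence and vigour heterogeneity), so synthetic LOSO accuracy sits in
  the high-80s/low-90s percent rather than near 100 % — deliberately
  informative, but not a claim about real-data accuracy.
* Ramp-bout frames are labelled by threshold crossings of the true speed
  trace; how such frames are best labelled in real protocols is an open
  design question, and the window-level strict-majority rule with
  tie-discard is a conservative choice.
* CWA/binary sensor formats are not parsed; any converter emitting the CSV
  dialect can feed the pipeline.
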