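# Methods

## Problem and pipeline

The package screens neonatal phonocardiograms for audible signatures of
patent ductus arteriosus (PDA) and other congenital heart defects (CHD).
Input is one mono WAV recording per auscultation point (five points per
patient: aortic, pulmonic, tricuspid, mitral, left sternal border) plus a
manual segmentation of each recording into heartbeat cycles and, within
each cycle, the four phases S1, systole (m1), S2, diastole (m2). The
pipeline is: resample to 2 kHz → extract 200 features per cycle →
aggregate across cycles/points → boosted-tree classifier → one probability
per patient → ROC AUC against the echocardiography label. Two binary
tasks are supported, PDA vs healthy and CHD vs healthy; the third
diagnosis group is excluded from both training and evaluation of a task.

## Synthetic cohorts

Clinical neonatal PCG is sensitive and scarce, so the simulator provides
labelled cohorts with exact ground-truth boundaries. Each cycle is built
at 2 kHz from four phases: S1 and S2 are exponentially decaying sinusoid
bursts (centre frequencies 90 and 110 Hz, amplitudes 0.4/0.3, decay time
0.2 of the burst length, random phase) on top of white recording noise
(`noise_sd`, default 0.01). A CHD patient receives a murmur — white noise
of amplitude `murmur_gain · point_gain · noise_sd` shaped by the same
zero-phase Butterworth band-pass the feature stage uses — in m1 only; a
PDA patient in both m1 and m2 (continuous murmur). Defaults: heart rate
143 ± 7 bpm (cycle ≈ 0.42 s, truncated to 60–250 bpm per cycle), S1 70 ms,
S2 50 ms, systole 45% of the remaining silent time, murmur band
200–400 Hz, five cycles per point, per-point murmur gains
(0.5, 1.0, 0.5, 0.5, 0.5) so the PDA murmur is loudest at the pulmonic
point. All randomness flows through one generator per patient, seeded
deterministically from the cohort master seed.

What the simulator does **not** model: real hemodynamics (murmur spectra
and envelopes are noise bursts, not turbulence), respiration and crying
artefacts, sensor coupling variation, heart-rate trends within a
recording, or ambiguous segmentations. Consequently, passing tests show
that the pipeline recovers the class-conditional acoustic structure it is
pointed at and that its evaluation machinery is honest — they do not
certify clinical performance, which can only be established on real
recordings.

## Feature census

Exactly 200 features per cycle:

* all four intervals (29 each, 116 total): raw energy, zero-crossing
  count; energy/RMS in linear and dB for the 25–1000 Hz wide band and the
  five sub-bands 25–45 / 45–80 / 80–200 / 200–400 / 400–1000 Hz; spectral
  centroid over (0, 200] Hz; centroid deviation from the per-point mean in
  octaves; interval duration relative to the point's mean cycle length;
* S1 and S2 only (22 each): absolute extrema values and normalised times,
  local-extrema and zero-crossing timing statistics (mean/sd of times and
  of time differences, counts), derivative-discontinuity count,
  max-position skewness;
* m1 and m2 only (19 each): envelope second-order polynomial
  coefficients, quarter energies, whole-interval mean/sd, quarter
  means/sds, zeros per second, max-position skewness;
* two per-point globals: beats per minute and the cycle length relative
  to the point mean.

Numerical conventions:

* filters are 4th-order Butterworth, applied forward–backward
  (zero-phase); a band reaching the 1 kHz Nyquist degrades to a high-pass,
  a band starting at 0 to a low-pass; the pad length is clamped for short
  intervals;
* dB values are `10·log10(x + 1e-12)` (floor −120 dB);
* a zero crossing is counted between consecutive samples of opposite
  strict sign, or when zero samples separate opposite signs;
* the spectral centroid is magnitude-weighted over DFT bins in
  (0, 200] Hz, excluding DC; degenerate (no in-band magnitude) returns 0.
  A centroid rather than a spectral peak was chosen for the "central
  frequency" because it is continuous in the signal and stable on short,
  noisy intervals;
* the envelope is the magnitude of the analytic (Hilbert) signal smoothed
  by a 10 ms moving average; the polynomial is fitted over time normalised
  to [0, 1];
* local extrema are strict; plateaus count once at their first sample;
  event times are normalised by interval length; statistics over empty
  event sets are 0;
* quarters are `floor(n/4)` samples, remainder to the last quarter;
* derivative discontinuities are isolated runs where the second
  difference deviates from its median by more than 4 robust MADs, with an
  absolute floor (1e-9 of the amplitude scale) so float jitter on
  perfectly smooth signals never counts; the multiplier 4 makes the
  detector scale-free and insensitive to smooth oscillation;
* no amplitude normalisation is applied before feature extraction; the dB
  features provide scale robustness.

The per-point references (mean cycle duration, mean centroid per interval
label) are computed over all cycles of that auscultation point.

## Boosting

The reference booster is an exact implementation of regularised
second-order boosting with logistic loss: gradient g = p − y, hessian
h = p(1 − p), leaf weight w* = −G/(H+λ) scaled by the learning rate η,
split gain ½[G_L²/(H_L+λ) + G_R²/(H_R+λ) − G²/(H+λ)] − γ maximised by
exhaustive search over midpoints between consecutive distinct feature
values. A split is added only if its gain (γ already subtracted) is
strictly positive; gain ties break to the lower feature index, then the
lower threshold, making fits without subsampling fully deterministic. The
base score is the log-odds of the training prevalence. Row/column
subsampling draw without replacement from the run's seeded generator.
Defaults: η 0.03, depth 3, subsample 0.9, colsample 0.9, λ 1, γ 0.

The production path delegates training to xgboost with settings that
honour the same contract: `tree_method=exact`, `min_child_weight=0` (the
reference has no minimum-child-weight notion), base score = prevalence,
single thread (determinism), seed per fit. Early stopping monitors
validation AUC with patience 50 over at most 1000 rounds; the retained
model is the **last** round attaining the maximum validation AUC. The
last-argmax tie-break matters on easily separable data, where AUC
saturates immediately: the longer-trained model has larger margins, so
probabilities pooled across CV folds remain comparable instead of
collapsing to fold-specific prevalences. Agreement between the two paths
(identical parameters, no subsampling) is enforced by a cross-
implementation test at 0.05 RMS on per-instance probabilities.

Gain importance sums each feature's split gains over all trees and
ensemble members; ties in total gain rank by canonical feature order.
Top-N selection takes the first N names of that ranking.

## Evaluation

AUC is computed as the rank statistic (probability that a random positive
outscores a random negative, ties ½) via average ranks; it is exactly
equal to O(n²) pairwise counting.

Patient-independent folds assign whole patients to folds with stratified
k-fold (fold sizes within one patient, per-fold class counts within one of
proportional). Patient-dependent splits shuffle at row (cycle) level with
a seeded stratified shuffle. Requested fold counts clamp to the
minority-class size so small cohorts still evaluate. The three protocols:

* Setting 1: patient-independent outer and inner splits;
* Setting 2: patient-independent outer, cycle-level inner (leaks identity
  into model selection / early stopping);
* Setting 3: cycle-level everywhere (leaks into the test estimate).

Each outer training set yields a 10-model ensemble (10-fold inner CV,
each member early-stopped on its held-out fold; members whose validation
fold is single-class train without early stopping). Predictions are the
ensemble mean. Reported numbers: validation AUC mean ± sd over all inner
folds (the instance-level quantity early stopping maximises), training
AUC per outer fold, and a single test AUC over pooled out-of-fold
probabilities aggregated to one value per patient (every row is
out-of-fold exactly once in all settings). Hyperparameter search, when
requested, evaluates each grid point by mean out-of-fold AUC over five
seeded 2-fold splits inside the outer training set, with ties resolved to
the first grid entry; the default grid spans depth {2,3,4,5} ×
subsample {0.5,0.7,0.9} × colsample {0.5,0.7,0.9}. The heavier
experiment drivers default to untuned printed parameters; tuning is
opt-in via the `grid` argument.

The leakage experiment plants a fixed per-patient offset (drawn once per
patient, sd = scale × column sd) into every feature column, emulating
patient-specific nuisance structure (sensor placement, skin coupling);
with a weak murmur this makes patient identity far easier to learn than
pathology, so the Setting 3 − Setting 1 gap isolates identity leakage.

## Problem sizes used by the test and acceptance runs

The end-to-end checks use a 120-patient cohort (60 healthy / 40 PDA /
20 CHD, five cycles per point, murmur gain 3); the leakage contrast uses
24 patients (12/12) with three cycles per point, murmur gain 0.8, offset
scale 1.0, five seeds, and 60 boosting rounds for both settings (the
comparison is paired, so the cap is fair); booster-math verification uses
twenty 50×8 datasets and AUC verification two hundred seeded cases.
These sizes were chosen as the smallest at which the studied effects are
unambiguous.

## Known limitations

* The simulator's murmur is spectrally flat within its band; real PDA
  murmurs are machinery-like with harmonic structure and envelope
  modulation.
* Validation AUC is instance-level (what early stopping sees), while test
  AUC is patient-level; on per-patient aggregated representations the two
  coincide.
* Segmentation is assumed given (manual in the clinical workflow); no
  automatic segmenter is included.
* The grid-search path is O(|grid| · 10 fits) per outer fold and is
  therefore opt-in; the shipped defaults reproduce the printed classifier
  settings instead.
* Confidence intervals for AUCs are not computed.
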