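# Methods

`vitalrep` classifies perioperative heart-failure risk from intraoperative
vital-sign monitoring series. Five channels per patient — heart rate (hr,
bpm), non-invasive systolic and diastolic blood pressure (nisysbp/nidiasbp,
mmHg), oxygen saturation (spo2, %), and pulse pressure (pp = nisysbp −
nidiasbp, mmHg) — are transformed into three alternative per-patient
representations, each fed to a supervised classifier benchmark. This note
records the model choices, parameter conventions, and the limits of what the
synthetic experiments demonstrate.

## Data model and preprocessing

Series are irregular timestamped points; the package never interpolates.
Pipelines needing fixed windows assign points to windows by membership.
Pulse pressure is derived by exact-timestamp alignment of the two pressure
channels (pp_t = sys_t − dia_t on the timestamp intersection). Records
missing any of the five channels are excluded from modelling with a logged
count rather than silently imputed. Z-normalization is per patient, per
channel, with population (1/N) variance — matching the moment convention of
the statistical features and the standard-normal assumption behind SAX
breakpoints; constant series cannot be normalized and the affected patient is
skipped by the text pipeline with a log entry.

## Statistical representation (90 features)

For each channel, nine summary statistics — mean, standard deviation, min,
25/50/75% quantiles, max, skewness, kurtosis — are computed on the raw series
and on its first-order difference: 2 × 9 × 5 = 90 named features
(`mean_hr`, `min_diff_hr`, `diff-kurt_diff_pp`, ...; the diastolic channel is
spelled `nidiasbpe` in feature names, following the naming scheme this
feature set comes from). Conventions that differ from common library
defaults, fixed deliberately as part of this feature set's definition:

* population (1/T) moments — no Bessel correction;
* kurtosis is the raw standardized fourth moment (≈3 for normal data), not
  excess kurtosis;
* quantiles locate rank (n+1)p with linear interpolation between order
  statistics (the 25% quantile of 7 sorted points is exactly the rank-2
  value); the rank is clipped to [1, n] for tiny samples;
* a zero-variance series gets skew = kurt = 0 with a degeneracy flag rather
  than NaN, so downstream matrices stay numeric.

The feature grid is fully regular (18 features per channel). One published
listing of this feature set omits the diff-kurtosis entry for pulse pressure
(89 names) while stating a 90-feature total; the regular 90-feature grid is
implemented.

The correlation filter drops (a) zero-variance columns (Pearson r undefined)
and (b) the later column of any pair with |r| ≥ 0.99 — operationalizing the
removal of "zero-importance" features via correlation analysis, which is
ambiguous as prose; both the threshold and the whole filter are configurable.

## Text representation (PAA → SAX → phrases → LDA)

Each z-normalized channel is reduced by piecewise aggregate approximation
(one mean per 3-minute window; only windows fully covered by the recording
produce a segment), discretized by SAX with a = 5 equiprobable standard-normal
breakpoints (alphabet size 5 by default — standard SAX practice — and
configurable), and each non-overlapping run of 3 letters becomes a
four-field phrase `<level> <channel> <modifier> <movement>`. The rule table
mapping letter shape and window statistics to the phrase vocabulary is this
package's canonical definition (shape → movement; window mean z at ±0.43 →
level; |net z-change| ≥ 1 separates rapidly/slowly, its sign separates
upward/downward). A patient's document concatenates channels in fixed order
(a per-channel document mode exists behind a flag). With the default 180-min,
1/min design this gives 60 letters and 20 phrases per channel — 100 phrases
per patient.

LDA with k = 5 topics by default and symmetric priors α = η = 1/k is fitted on phrase counts, each
phrase being one vocabulary token; scikit-learn's batch variational
implementation is used with a fixed `random_state`, and each patient is
represented by the normalized 5-topic posterior (a point on the 4-simplex).

## Image representation (grid + CNN)

Each channel is rasterized onto an m × n grid over its own time–value
bounding box (m = n = 16 by default; per-series bounds, with explicit bounds
available for cross-patient comparability): time into n equal columns, value
into m equal rows, cell (i, j) counting the points in that rectangle. Bins
are half-open with the top bin closed, a point on an interior edge going to
the upper bin; every point lands in exactly one cell, so counts sum to the
series length. The five grids are stacked into a (5, m, n) tensor, each
channel scaled by its max cell count by default for training stability.

The classifier is a deliberately small CNN, implemented in numpy: two blocks
of 3×3 same-padded convolution + ReLU + 2×2 max-pool (8 and 16 channels), a
32-unit dense ReLU layer, and a 2-way softmax, trained with Adam (lr 1e-3,
batch 32) on cross-entropy for at most 50 epochs with early stopping on
validation loss (patience 10, best weights restored). All randomness flows
from one seeded generator and the arithmetic is deterministic, so training is
bit-reproducible on a given platform. At this input size (5×16×16, a few
hundred patients) CPU training takes seconds per run.

## Evaluation protocol

A stratified 80/20 train/test split is fixed first and shared by all three
representations; 10-fold stratified CV inside the training portion (9:1)
yields fold-level validation metrics, after which each classifier is refit on
the full training portion and scored once on the held-out 20%. Both views are
reported: the single test split is the headline protocol but is high-variance
at n = 252, so fold dispersion is kept alongside.

Eight classifiers run on tabular features with fixed, serialized
hyper-parameters: AdaBoost (100 estimators), decision tree (gini, default
splits), SVM (RBF kernel, ranked by its decision function), logistic regression
(l2), Gaussian naive Bayes, random forest (100), MLP (hidden layers (5, 2)),
and gradient-boosted trees (200). Everything else stays at backend defaults
and is recorded in the run sidecar. The CNN plays the classifier role for the
image representation, with one stratified fold of the training portion as its
early-stopping validation set. Hard-label metrics (sensitivity/TPR,
specificity/TNR, F1, accuracy) threshold predicted probability at 0.5
(configurable); a metric with a zero denominator is reported as NaN with a
reason, never as 0. ROC/AUC uses the trapezoidal rule (equivalently the
tie-corrected rank statistic).

## Synthetic cohort generator

Real intraoperative monitoring data of this kind cannot be shared, so the
package ships a generator that emulates its shape: 84 positive and 168
negative patients (a 1:2 case:control design), 180 minutes sampled
every 60 s, per-channel baselines hr 75±8 bpm, nisysbp 120±12 mmHg, nidiasbp
70±8 mmHg, spo2 98±1 %. Noise is stationary AR(1) (ρ = 0.8) plus a bounded
slow random walk (step 0.1 channel-sd, clipped at ±2 sd) — the simplest
process with realistic short-range autocorrelation and baseline wander.
SpO2 is clipped to ≤ 100 and systolic is kept above diastolic (violations
resampled), so pp > 0 always.

Positives receive a signature scaled by `effect`: +8·effect bpm mean heart
rate, heart-rate variance ×(1+effect), a linear SpO2 decline of −2·effect %
over the final third, and pulse-pressure widening of +10·effect mmHg by the
end (applied to the systolic channel). The signature deliberately touches all
three representations: the mean/variance shift is visible to summary
statistics, the trends to SAX shape phrases, and the altered time–value point
distribution to the grids. `effect=0` makes the labels independent of the
data (a true null); the default is `effect=1`.

What passing synthetic tests does and does not show: they demonstrate that
each pipeline is correctly wired end-to-end, chance-level on null data, and
able to recover a class signal of the kind it is designed to see. They do not
emulate real hemodynamics (no cardiovascular ODEs, no artifacts, no
inter-channel physiological coupling beyond pp = sys − dia), so synthetic
AUCs say nothing quantitative about performance on hospital data.

## Numerical choices and degenerate inputs

* SAX: a value exactly on a breakpoint maps to the upper letter; grids use
  the same upper-bin tie rule on cell edges.
* PAA with ω ∤ N fractionally weights boundary points so the mean of segment
  means equals the input mean to ≤1e-12.
* Constant series: statistics get the degeneracy policy above; grids put all
  points in one row; z-normalization refuses (caller skips).
* Quantile ranks are clipped into [1, n]; AUC ties count one half.
* CSVs are written with `%.17g` and read with round-trip float parsing, so a
  written cohort reloads bit-identically.

## Seed-averaged calibration checks

The null-calibration and signal-recovery checks (acceptance tests and
`scripts/acceptance.py`) average held-out AUC over 5 independently simulated
cohorts of the default 252-patient design: a single 51-patient test split has
an AUC standard error near 0.08, so single-cohort checks would be dominated
by split noise. Null calibration uses each representation's headline
classifier (GBDT for statistics, naive Bayes for topics, the CNN for images);
signal recovery takes the best of the eight classifiers per cohort. Typical
values at effect=2: statistical ≈ 1.0, image ≈ 0.97, text ≈ 0.77 — the text
pipeline compresses 100 phrases to 5 unsupervised topic weights and is
expected to be the weakest of the three.

## Known limitations

* The rule-engine vocabulary mapping and the SAX alphabet size are canonical
  package definitions, not independently validated clinical conventions.
* LDA topics are unsupervised; with small cohorts the 5-topic compression can
  discard label-relevant phrases (visible as the text pipeline's wide AUC
  spread across cohort seeds).
* The CNN is bit-reproducible only per platform/BLAS; cross-platform
  determinism is not guaranteed.
* `benchmark_all` requires every complete patient to survive the text
  pipeline so all representations share folds; cohorts with constant or
  too-short series must be cleaned first.
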