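# Methods

This note documents the models, conventions and design choices behind
pupilscreen: what each stage computes, which knobs matter, what the
synthetic cohorts do and do not emulate, and where genuinely open design
questions were settled.

## Data model

A trial is a uniformly sampled pupil-diameter series (`t_ms` strictly
increasing with constant spacing; diameter in arbitrary units). Missing
samples — blinks, tracking dropouts — are IEEE NaN, the distinguished
missing marker of the numpy/pandas ecosystem, never a sentinel value in
the data range. Group labels are the strings `ADHD`/`CTRL` in files and
a binary enum (`ADHD_POSITIVE`/`CONTROL`) in memory; the mapping happens
only at the I/O boundary. Feature-matrix CSVs are written with 17
significant digits and read with round-trip float parsing, so
write-then-read reproduces every value bit-for-bit.

Sample indexing is 0-based; millisecond windows convert to indices by
floor division by the sample period, and all windows are half-open
`[start, end)`.

## Preprocessing

Order of operations: **exclude → impute → reduce**.

1. **Exclusion.** A trial is dropped iff its missing fraction is
   *strictly* greater than `max_missing_fraction` (default 0.8); a trial
   at exactly the boundary is kept. Missingness is assessed before
   imputation — assessing after would make the criterion vacuous.
2. **Imputation.** Interior gaps are filled by a cubic spline through
   all observed points. The **not-a-knot** boundary condition is used
   because it reproduces any cubic polynomial trend exactly regardless
   of gap placement; a natural spline (zero end curvature) was
   considered and rejected after measurement — its end condition is
   inconsistent with a curved series and displaces interpolated values
   by ~1e-2 even in mid-series (measured on p(t) = t³ − 2t² + 1 with one
   interior gap). Leading/trailing missing runs are filled by
   nearest-observed-value extension, since extrapolating a cubic is
   unstable. Fewer than 4 observed samples is an error (such trials
   should have been excluded).
3. **Reduction.** Non-overlapping block means of width `window_ms`
   (default 16 ms): output sample k is the mean of the k-th block, time-
   stamped at the block start; a trailing partial block is discarded.
   This is decimation, not a sliding window — the only reading under
   which an 8000-sample, 1 kHz trial maps to exactly 500 samples. The
   global mean is preserved exactly when the window divides the length.
   All features are computed on the reduced series.

## Custom feature catalogue (22 items)

Built on the dilation metrics

V_i = (P_i − P_0)/(T_i − T_0),  A_i = (V_i − V_0)/(T_i − T_0),
AV_i = Σ_{j≤i} V_j,

with these conventions:

* Velocity at the origin sample is undefined and stored as 0;
  acceleration additionally takes V_0 to be the velocity at the *first
  post-origin sample* (the earliest index where velocity exists), so
  A at the first two positions is 0.
* "Before the probe" quantities use the trial start as origin; "after
  the probe" quantities re-anchor the origin at the probe sample
  (default 5000 ms). The before/after index sets partition the trial.
* Window items (max size in 5000–7000 ms, max in 0–5000, min in
  6500–8000, mean in 5500–7000, accelerations in 5000–7000) read the
  extreme/mean *value* in the window. Windows are millisecond constants
  of the canonical 8 s / probe-at-5 s layout; for scaled trials they are
  rescaled affinely within the pre- and post-probe spans (the default
  timing reproduces the literal windows exactly).
* Moments are population estimators: biased variance/std, standardized
  third moment for skew, Fisher (excess) kurtosis without bias
  correction; a constant series gets skew = kurtosis = 0 by convention.
* Items 16–18 are the printed differences (15−14, 13−14, 11−14). Item
  19 as printed duplicates item 17 and is implemented literally; the
  config switch `item19_interpretation =
  "velocity_after_minus_accum_after"` substitutes the plausible
  alternative reading (item 13 − item 15) without changing defaults.
  The duplicate is kept deliberately rather than silently "fixed".

`list_custom_features()` returns the frozen 22-name catalogue in order.

## General features

Implemented from scratch and verified in the tests against independent
literal implementations (and scipy/sklearn where they compute the same
quantity):

* **absolute energy** Σx².
* **FFT real coefficient** Re X_k, k = 2 by default.
* **change-quantiles variance**: population variance of |x_{i+1} − x_i|
  over consecutive pairs whose *both* endpoints lie inside the
  [q(0.4), q(0.8)] corridor (linear-interpolation quantiles, endpoints
  inclusive); 0 when fewer than two pairs qualify.
* **approximate entropy** ApEn(m, r) per Pincus: Φ_m − Φ_{m+1} with
  self-matches included and Chebyshev distance; m = 2, r = 0.2 × the
  series' population std (the r value is unstated in the source
  protocol; 0.2·σ is the standard Pincus convention and is exposed as
  `r_factor`). Constant series → 0.
* **number of peaks**: indices strictly greater than all n = 10
  neighbours on each side; series of length ≤ 2n return 0 with a
  warning.
* **linear trend stderr**: sqrt((SSE/(N−2)) / Σ(i−ī)²) of the OLS fit
  against the sample index.
* The six standard moments, same conventions as the custom catalogue.

The registry (`FeatureSpec`) is the extension point for further
features; only the discriminative set above is re-implemented exactly —
reproducing a full multi-hundred-feature third-party catalogue would add
no verifiable surface. Aggregation computes each feature per trial and
averages per subject; a feature failing on some trials of a subject
averages over the successes (logged), failing on all of them is an
error naming subject and feature.

## Statistics

* **Mann–Whitney U** (descriptive ranking): U_x from midranks, two-sided
  p. Exact by full enumeration of label assignments when the pooled
  sample is ≤ 12 and untied (enumeration is desk-fast there); otherwise
  the normal approximation with tie correction and 0.5 continuity
  correction. U_x + U_y = n_x·n_y always.
* **One-way ANOVA F** (selection inside CV folds): F = MSB/MSW with df
  (1, n−2). For two groups this ranks identically to |t| and to the
  squared point-biserial correlation, so no separate correlation path
  exists. Zero within-variance with unequal means → (∞, 0), documented.
* Ranking sorts by (p, name) so it is deterministic and invariant to
  subject-row permutation; constant columns get p = 1 by convention.
  P-values are reported raw; a Benjamini–Hochberg option exists but is
  off by default.

## Nested cross-validation

Per repetition (default 40; 30–50 is the intended range), subjects are
re-shuffled and split into stratified outer folds (default 10 —
stratification is an addition: with a 28/22 imbalance, unstratified
10-fold splits risk single-class folds). Per outer fold:

1. top-k features by ANOVA-F on the *training* subjects (k = 9);
2. z-scoring fitted on the training folds (an addition required by
   distance/margin-based models);
3. stratified inner 5-fold grid search maximising AUROC over a small
   fixed per-family grid (logistic C ∈ {0.01, 0.1, 1, 10}; SVM
   linear/RBF × C ∈ {0.1, 1, 10}; tree depth {2, 3, 5, ∞}; Gaussian NB
   smoothing; kNN k ∈ {3, 5, 7}; random forest depth {3, ∞} at 100
   trees) — modest on purpose: reproducible and fast, no silent tuning;
4. refit on the full training part, score the held-out fold once.

Class predictions use each model's 0.5-probability decision (the
`predict` path; the SVM uses its margin sign — it is fitted without
Platt scaling and scored by decision function). AUROC uses the rank
(Mann–Whitney) formulation with half credit for ties, identical to the
trapezoidal area under the pooled ROC. The aggregate "±" is the
standard error of the per-repetition means (`ci_mode="ci95"` switches
to a 95% normal half-width); the source protocol prints "±" without
defining it, so the definition is stated here and in the report config.

The leakage guard is executable: `nested_cv(corrupt_test=...)` replaces
each held-out fold's feature block *after* selection and fitting; the
selected features and per-fold model fingerprints (a digest of the
fitted model's scores on its own training data) must be — and are,
under test — identical to an uncorrupted run.

## Synthetic cohorts

Per trial: `baseline_s + evoked(t) + AR(1) + fast jitter`, with
`evoked(t) = A_s(1 − e^{−(t−probe)/τ_s})` from the probe, relaxing
exponentially after the late-trial decay point (2/3 into the post-probe
span; decay constant half the span). Per-subject parameters are drawn
once per subject from group-level normals (truncated positive);
amplitudes get an 8% trial-level jitter. Noise has two parts at 1 kHz:
a slow AR(1) (ρ = 0.995, marginal sd σ_s) and a fast AR(1)
(ρ = 0.9, ~10 ms correlation) standing in for erratic pupillary
micro-movement — a short but non-zero correlation time is needed
because strictly white noise would be annihilated by the 16 ms block
averaging. Blinks are MCAR Poisson onsets (0.15/s) with lognormal
durations (median 120 ms); 2% of trials are "catastrophic" (85–95%
missing) so the exclusion rule has real work.

Default design: 28 ADHD-positive + 22 control subjects, 160 trials each,
8000 ms at 1 kHz, probe at 5000 ms. Under `effect="strong"` the control
group has larger amplitude (0.72 vs 0.54), faster time constant (420 vs
620 ms) and larger slow-noise sd (0.145 vs 0.105), while the ADHD group
has triple the fast jitter (0.018 vs 0.006) — yielding the target
orderings: control > ADHD for post-probe velocity, peak size and overall
std; ADHD > control for approximate entropy and peak counts.
`effect="null"` forces identical (midpoint) parameters;
`effect="moderate"` halves the gaps. Magnitudes were chosen once so
that the strong effect puts nested-CV SVM AUROC in the 0.85–0.95 range
at the scaled demo size (measured 0.86–0.94 across cohort seeds) — the
regime of a convincingly separable but imperfect biomarker — and they
target the *orderings* of the real study's group medians, not their
values, which are not recoverable from summary statistics.

What the generator does **not** emulate: luminance confounds, biophysical
pupil dynamics, task-performance structure (correct/incorrect trials),
non-stationarity across a session, or informative (non-MCAR)
missingness. Passing tests on these cohorts therefore demonstrate that
the pipeline recovers structure it is designed to detect and reports
chance under the null — not clinical performance on real recordings.

## Problem sizes in the tests

The test and acceptance runs use the full trial layout (8 s at 1 kHz,
50 subjects) with 6 trials per subject instead of 160, and 10–30 CV
repetitions instead of 40 — per-subject averaging over 6 trials already
stabilises the features, and the repetition count only narrows the
reported standard error. The replicate test for the headline features
(mean velocity after the probe, pupil-size std: Mann–Whitney p < 0.05
with control > ADHD) uses 20 generator seeds and requires ≥ 90% hits.

## Known limitations

* Catalogue item 19 is a printed duplicate (see above); both readings
  are available but neither is authoritative.
* The exact-enumeration Mann–Whitney path requires untied pooled
  samples; ties always take the corrected normal approximation, which
  is approximate for very small n.
* ApEn is O(N²) in series length; fine at 500 samples, not intended for
  unreduced 8000-sample series in bulk.
* RadViz requires non-constant features (min-max normalization is
  undefined otherwise) and places all-zero rows at the origin by
  convention.
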