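# Methods

## Signal model and preprocessing

An overnight SpO2 recording is modelled as a uniformly sampled percent-
saturation trace with a per-sample validity mask. On load every trace is
resampled to a fixed analysis rate of 1 Hz by block median. Saturation
dynamics are slow relative to 1 Hz, the event rule below is stated in
seconds, and a fixed rate makes the duration threshold an integer sample
count independent of the recording device; the block median is robust to
single-sample artifacts within a block.

Validity rules: a sample is invalid if it is non-finite, equal to 0 (the
common dropout convention of oximeters), or outside [50, 100] % — 50 % is
below any plausible pediatric saturation. Runs of invalid samples longer
than 60 s are removed from *analyzable time*; shorter gaps keep their
place in the denominator but contribute no events or low-saturation time.
These artifact rules are this package's own: reference datasets do not
document their artifact handling, so the thresholds are configurable.
`validate_signal` is idempotent and records analyzable seconds on the
record.

## Desaturation events and features

The pre-event baseline at sample *i* is the mean of valid samples in the
preceding 120 s window, defined once at least 30 s of valid history
exists. An event opens at the first valid sample at or below
(baseline − d_min), where d_min = 2 % is the smallest configured depth;
the baseline is frozen at its onset value — a rolling baseline would
absorb long desaturations and truncate them — and the event closes on the
first sample back above the frozen level. Events must last strictly more
than 10 s (≥ 11 samples at 1 Hz). A candidate interrupted by an invalid
sample is discarded: neither its depth nor duration can be certified
through a dropout. Detections at deeper thresholds are necessarily
sub-intervals of the d_min detection under a frozen baseline, so each
physical desaturation is recorded once, with `depth_pct` equal to the
maximum drop below the frozen baseline.

Features: `ndesXph` is the count of events with depth ≥ X % divided by
analyzable hours; `odi3`/`odi4` are the same quantities at 3 %/4 % and are
therefore numerically identical to `ndes3ph`/`ndes4ph` here (source
datasets may derive their ODI from an independently configured detector;
this package computes both from one detector and documents the
equivalence). `pctleT` is 100 × (valid seconds at saturation ≤ T) /
analyzable seconds. Two consequences worth knowing: events closer together
than the baseline window are detected against a baseline contaminated by
the previous event (inherent to the definition; the synthetic generator
spaces events beyond the window so ground truth stays exact), and
`ndesXph` is a rate, not a raw count, so nights of different lengths are
comparable.

Labels: at-risk iff AHI ≥ 5 events/h; severity bins normal < 5 ≤ mild <
15 ≤ moderate < 30 ≤ severe. The AHI always comes from an external
reference study — it is never computed from SpO2.

## Cohort statistics and feature reduction

Z-scoring uses the sample (n−1) standard deviation. By default the
standardizer is fitted on training folds only and applied to test folds;
a `standardize_scope: dataset` switch provides the whole-dataset
convention some studies use, at the cost of a small optimistic bias.
Zero-variance features are dropped with a warning rather than producing
infinities.

Correlation-based reduction groups features by the transitive closure of
|Pearson r| > 0.9 and keeps, per cluster, the member most correlated (in
absolute value) with AHI — falling back to canonical feature order on ties
or when AHI is absent. Transitive clustering matches the empirically
observed structure: the six desaturation-rate features form one tight
cluster. Spearman correlation is available by argument given the heavy
skew of these features. Mutual-information selection (for SVM/AdaBoost)
uses the k-nearest-neighbour estimator with a fixed seed; k defaults to
the number of features surviving correlation reduction.

Group comparison reports per-feature means ± SD by group, Shapiro-Wilk
normality p-values and two-sided Mann-Whitney U p-values, flagging
p ≤ 0.05. No multiple-testing correction is applied, matching the
single-screen usage.

## Classifiers and nested cross-validation

Grids: LR C and SVM C on log grids over [0.01, 100] and SVM γ over
[0.001, 100], five points per decade by default (density configurable);
AdaBoost learning rate on a 10-point linear grid over [0.01, 1] and
estimator counts 50..1000 in steps of 10. The AdaBoost base learner is a
depth-1 decision tree (stump), the standard weak learner. Class imbalance
is handled by seeded undersampling of the majority class before CV.

Nested CV is stratified 15-fold outside, 5-fold inside (the inner depth is
a runtime choice; stratification guarantees both classes in every fold).
Inside each outer training set, in order: standardizer fit, feature
selection (correlation reduction for LR, whose L1 penalty then performs
the final shrinkage along its regularisation path; MI ranking for
SVM/AdaBoost), exhaustive inner grid search maximizing mean inner-fold
AUC (first-best tie break in grid iteration order), refit on the full
outer-training set, evaluation on the held-out fold. Binary decisions use
the 0.5 posterior threshold (LR/AdaBoost) or the 0 margin (SVM); the
continuous risk score feeds the ROC. KPIs are reported as across-fold
mean ± SD rather than pooled counts, with a pooled mode available.
Everything is a deterministic function of the seed.

A leakage canary test guards the fold discipline: a feature made
informative only on one outer test fold must leave the cross-validated
AUC in the null band.

## Metrics

Sensitivity TP/(TP+FN), PPV TP/(TP+FP), specificity TN/(TN+FP), NPV
TN/(TN+FN), accuracy (TP+TN)/N, F1 2TP/(2TP+FP+FN); positive = at-risk.
Zero-denominator rates surface as flagged NaN, never as 0, so fold
averages are not silently distorted. The ROC is the empirical curve with
ties advanced in a single simultaneous step; its trapezoidal area equals
the normalised Mann-Whitney U statistic, which the tests verify against
an independent U computation. Rates are stored as fractions and formatted
×100 only in reports.

## Synthetic data: what it emulates, and what it does not

`make_trace` builds a 1 Hz night: piecewise-constant baseline (default
97 %, 30-min segments jittered ±0.4 %), Gaussian sensor noise (default
SD 0.2 %), trapezoidal desaturation dips (ramp 0.5 %/s) with categorical
depths defaulting to mid-class values 2.5–7.5 % and below-threshold
durations uniform on [12, 60] s, and optional zero-run dropouts kept
clear of events. Event onsets follow a hard-core renewal process: after
each event, a 150-s minimum gap (wider than the 120-s baseline window, so
ground truth is individually recoverable) plus an exponential wait whose
mean is set so the marginal onset rate equals the nominal events/hour.
Counts over a night are then slightly under-dispersed relative to
Poisson, so Poisson-band recovery checks are conservative.

`make_cohort` draws the eight features per group from Gaussians truncated
at 0, with means/SDs defaulting to the published summary statistics of a
197-healthy / 256-at-risk pediatric cohort. Truncation shifts the
realised mean upward where the floor is close (markedly for the
cumulative-time indices, whose published SDs exceed their means); moment
tests therefore compare against the truncated distribution's theoretical
mean. `coupling="clustered"` routes a shared latent severity factor
(ρ = 0.95) through the six desaturation-rate features to reproduce their
observed |r| > 0.9 cluster — values are clipped at 0 in this mode, since
rejection sampling would break the coupling. A synthetic AHI consistent
with the class (healthy uniform [0, 5), at-risk uniform [5, 30)) is
attached; it is drawn independently of the features given the class,
because only the class boundary matters downstream.

What passing tests on these generators shows — and does not. The
independent-features cohort carries the published marginal group
separations but none of the real inter-feature covariance (which is
unpublished beyond the |r| > 0.9 pattern); classifiers therefore reach
higher AUC on it than on clinical data, and results on it are an upper
bound, not a clinical claim. The trace generator does not model sleep
architecture, arousals, posture or device-specific smoothing. Note also
that features extracted from generated traces live on this detector's
scale, while the cohort generator reproduces published statistics from a
different extraction pipeline (its ndes2ph is an order of magnitude
larger); a deployed screening model must be trained on features from the
same extraction path it screens with.

## Numerical and design choices

- 0-based, half-open sample intervals throughout.
- Baseline means via cumulative sums (O(n) detection); the test oracle
  recomputes every window by direct summation.
- EDF writing is a minimal single-channel 16-bit implementation
  (quantisation step 100/65535 ≈ 0.0015 %); reading goes through `mne`
  with case-insensitive channel aliases (`SpO2`, `SaO2`, `OSAT`,
  `Oximetry`, configurable).
- The acceptance script averages 10 derived seeds of the LR pipeline at
  the published cohort sizes; one seed takes a few seconds on one CPU.
- Known limitations: no apnea-vs-hypopnea tagging, no probability
  calibration, no confidence intervals beyond across-fold SD, no
  imputation of missing features.
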