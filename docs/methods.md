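# Methods

## The analysis

A breath cohort is a samples × VOCs matrix of GC/MS concentrations
(ppb) with a binary diagnosis per sample. Three properties of such data
shape the whole design: class-conditional concentration distributions
are right-skewed and overlap heavily, so no single VOC separates the
classes; cohorts are imbalanced (many patients, few controls), which
biases a margin classifier toward the majority class; and the
informative signal lives in a small *combination* of compounds, which
is also what a portable multi-sensor instrument would need.

The pipeline therefore (i) balances the minority class by convex
interpolation between nearest neighbours, (ii) evaluates every VOC
subset with a leave-one-out cross-validated Gaussian-kernel SVM, and
(iii) selects compact panels using the support-vector count as a
parsimony criterion rather than chasing the maximal accuracy, which on
this kind of data is achieved by larger, more overfit subsets.

## Classifier

Soft-margin SVM, Gaussian kernel `exp(−‖x₁−x₂‖²/2σ²)` with σ = 1.5 and
C = 1000 on z-scored features; cancer is the positive class. σ is
dimensionless because features are standardized; C = 1000 makes the
margin hard enough that the support-vector count reflects the intrinsic
boundary complexity. Both are exposed in `KernelParams` and no tuning
loop is provided — the point of the analysis is subset comparison under
fixed hyperparameters, and a per-subset tuning loop would confound the
comparison. The dual is solved by libsvm (scikit-learn `SVC`); default
dual-gap tolerance 1e-3. Tests that compare two independently trained
models to each other (permutation invariance, an explicit
quadratic-programming solve of the same dual) tighten the tolerance to
1e-8 so solver error does not mask the property under test.

Normalization is refit inside every cross-validation fold on the
training portion only (sample SD, ddof = 1; a zero-variance feature
gets scale 1, making a constant column inert after centering). A
pre-fit scaler can be passed to `train_svm` for global-normalization
replication experiments, since legacy analyses sometimes standardized
once over all samples before cross-validating.

## Oversampling

SMOTE-style: choose an original minority sample at random, interpolate
one virtual sample uniformly on the open segment toward each of its
k = 2 nearest original minority neighbours (Euclidean distance in raw
ppb space; distance ties broken by sample index), repeat until the
minority count reaches the majority's 107. Interpolation happens in raw
concentration space because normalization is fold-dependent while the
oversampled set is generated once; synthetic points never seed further
synthesis. Each synthetic row records its two parents, which makes the
convexity property directly testable and enables the strict LOOCV mode.

## Cross-validation and metrics

Leave-one-out iterates over the 136 original samples only; the fixed
synthetic set always stays in training. TP/FN are counted over original
cancer samples, TN/FP over the 29 original controls, so
ACC·(P+N) = TPR·P + TNR·N holds as an exact integer identity (e.g. TPR
92.5% and TNR 75.9% on 107/29 force TP = 99, TN = 22, ACC = 121/136 =
89.0%). Because a held-out control's synthetic descendants remain in
training, the default procedure has a known optimistic leakage for TNR;
`strict=True` removes those descendants per fold and is the
leakage-free variant. Rates are kept at full precision internally and
rounded to one decimal only in tabular output.

## Ranking and frequency

Subsets are ordered by the metric at full precision with ties broken by
lower mean support-vector count, then lexicographically; competition
ranks (tied rows share a rank, the next rank skips: 1,2,2,2,2,6,…) are
assigned on the one-decimal rounded metric, matching how published
screening tables present ties. The frequency table counts how many of
the top-k subsets contain each VOC. The ordering of equal-rank rows
beyond the rank number is a reporting convention, not a reproducible
quantity.

## Stage analysis

"Distance from the boundary" is the signed decision value f(x)
(functional margin). The geometric distance differs by the constant
factor 1/‖w‖ within one model, so the within-model ordering — all the
analysis uses — is identical; the decision value avoids estimating ‖w‖
in the kernelized setting. Each staged cancer sample is scored by a
model trained on all other samples (train size = n − 1 per fold,
asserted), summarized per stage by median and IQR, and the
stage-vs-distance association is reported as a Spearman rank
correlation. One caveat is inherent to the RBF kernel: a sample pushed
far outside the training cloud has near-zero kernel similarity to every
support vector, so its decision value falls back toward the bias.
Extreme stage effects can therefore *reduce* apparent distances; the
generator's default stage gains are chosen inside the kernel's useful
range.

## Synthetic cohorts

`simulate` draws log-normal concentrations per VOC:
log-concentration ~ Normal(log_mean, log_sd), with cancer samples
shifted by δ·(1 + stage_gain·(stage − 1)) on the log scale. Log-normal
reproduces the non-negative, right-skewed, overlapping histograms of
real breath panels; δ is a log fold-change. The default 20-VOC panel
uses plausible baseline breath levels (isoprene ≈ 100 ppb, acetone ≈
500 ppb, halogenated species well below 1 ppb), δ = 0.7 and
stage_gain = 0.35 on five informative VOCs, log_sd = 0.8, imbalance
107/29, stage mix 55/15/28/9 and the study's smoking mix. Optional
additive ambient background and a detection floor (values below it
censored to 0) exercise the preprocessing steps. Ground truth — the
informative set and each sample's exact applied log-shift — is returned
with the data so recovery tests never reverse-engineer the generator.

What the generator does **not** emulate: between-VOC correlations
(metabolically related compounds co-vary in real breath), instrument
drift and batch effects, smoking-dependent concentration shifts, and
heavy-tailed contamination. Passing tests therefore demonstrate that
the machinery recovers planted multivariate structure under realistic
marginal distributions and imbalance — not that the specific published
VOC panel is biologically correct, which only new clinical data could
show.

## Problem sizes in the test suite

The full clinical-scale enumeration (1,048,575 subsets × 136 folds) is
supported through the cache/worker machinery but is a multi-day
single-core computation; the shipped studies use scaled-down versions
chosen to exercise every code path with comfortable statistical margins:

- exhaustive screen: 8 VOCs (255 subsets), cohort 107/29 oversampled to
  107/107;
- planted-recovery: 8 candidate VOCs with 2 informative (δ = 1.5,
  log_sd = 0.6), balanced 40/40, sizes 1–3, five seeds, success = the
  top-ACC subset contains both planted VOCs in ≥ 4/5 seeds;
- stage monotonicity: stage-balanced 160-patient cohorts (δ = 0.7,
  stage_gain = 0.35), five seeds, success = non-decreasing per-stage
  median distance I→IV with positive Spearman ρ in ≥ 4/5 seeds — stage
  balance is used because with the clinical stage mix only ~9 stage-IV
  patients exist and a 4-point median ordering is dominated by
  small-sample noise;
- univariate screen calibration: 200 null cohorts (20/20, 8 VOCs),
  Wilcoxon flag rate within 3 binomial SDs of α = 0.05.

## Numerical conventions and edge cases

- Wilcoxon rank-sum: exact distribution when the combined sample is
  ≤ 25 without ties, tie-corrected normal approximation otherwise; a
  VOC constant across both classes gets p = 1.0 (no evidence), never
  NaN.
- Background subtraction clamps negative results to 0 ppb by default
  (physical non-negativity) and logs the clamp count; `floor_at_zero=
  False` gives exact element-wise subtraction for diagnostics.
- Missing concentration cells are an error unless zero-imputation is
  requested explicitly (logged).
- Oversampling draws u on the open interval (0,1), so a synthetic point
  never exactly duplicates a parent.
- Decision value exactly 0 predicts healthy (ties break away from
  diagnosis).
- All stochastic components take explicit integer seeds
  (`numpy.random.default_rng`); identical seed + input is bit-identical
  output.

## Known limitations

- The fixed-once oversampling plus LOOCV replicates the published
  procedure but leaks information into TNR; the strict mode quantifies
  this but is not the default.
- Whether the original analysis standardized globally or per fold is
  not recoverable; per-fold is the default here as the leakage-free
  choice.
- The 63→20 VOC pre-filter of the original study (treatment-drug and
  near-detection-limit species) is not quantified anywhere; the panel
  is represented as an externally supplied include-list.
- Competition ranking on rounded metrics means rank tables depend on
  the one-decimal rounding convention; full-precision ordering is kept
  internally.
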