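# Methods

## Problem and model

Public expression compendia hold far more samples than usable ones: most
samples lack the clinical annotations (receptor status, race, treatment
response) that downstream analyses condition on. `metarecover` treats each
missing categorical variable as a supervised prediction problem — train on the
samples that carry the label, predict the rest — but optimizes a different
objective than a conventional classifier. The quantity of interest is
PCAP_x, the **Proportion of Cases Accurately Predicted**: the fraction of
data whose label can be recovered at a precision of at least x%. A model that
predicts everything at 80% precision is less useful for data rescue than one
that abstains on half the samples and is 95% precise on the rest.

A *model* here is the full pipeline combination: learning algorithm
(L1-logistic "lasso", random forest, gradient-boosted trees, RBF/linear SVM)
× normalization (RPM, quantile, rank) × oversampling choice (SMOTE on/off)
× gene-count mode (RFE-chosen ≤ 100, or a fixed 10 or 25). The minority class
is always coded +1 and is the "positive" class in precision/recall/F1.

## Normalization

Rank normalization replaces each sample's values with average-tied ranks
(1 = lowest, n = highest) and rescales by the rank sum n(n+1)/2 × 10⁻⁶, so
each sample sums to exactly 10⁶ and only within-sample order survives. The
tied-rank reading (average of the occupied rank *positions*) is the one under
which the rescaling constant is exact; the alternative reading (average of
the tied *values*) would break the sum invariant. RPM divides by the sample
total and multiplies by 10⁶. Quantile normalization replaces each rank-k
value with the mean rank-k value across samples; within-sample ties receive
the mean of the reference values over the tied span.

Rank and RPM are strictly per-sample, so any data split can be normalized
independently without leakage. Quantile normalization needs a reference
distribution: training folds build it, and held-out samples are mapped onto
the frozen training reference (`QuantileReference`), never onto their own.

## Training pipeline and leakage control

Inside every training fold, in order: normalize → Welch two-sample t-test
screen at α = 0.1 (two-sided; zero-variance genes dropped first; a gene with
zero variance in both classes and equal means gets p = 1) → per-gene
standardization on training statistics → recursive feature elimination →
SMOTE (if enabled) → randomized hyperparameter tuning → final fit. Validation
and test folds are never oversampled and never inform screening, feature
selection, scaling, or the quantile reference.

RFE drops the 10% lowest-importance genes per iteration (absolute
coefficients for linear models, impurity importances for trees; a
linear-kernel SVM ranks genes when the classifier is an RBF SVM). Auto mode
scores every candidate set of ≤ 100 genes by stratified 3-fold CV AUROC and
keeps the best; fixed mode stops at exactly k genes. If fewer genes pass
screening than a fixed k requires, all passing genes are kept with a warning.

SMOTE adds synthetic minority samples x_i + u·(x_nn − x_i), u ~ U(0,1), with
x_nn one of the k = 5 nearest minority neighbors (k capped at minority − 1),
until classes balance. It runs in selected-gene space, after RFE, so
synthetic points live in the space the classifier sees.

Hyperparameters come from 10 random draws per fit scored by mean stratified
3-fold CV AUROC (ties → first draw): penalty strength and SVM C log-uniform
on 10⁻³–10³, trees 100–1000, depth 2–10, learning rate log-uniform
0.01–0.3, SVM kernel ∈ {rbf, linear}. The spaces are a module-level default
table that callers can override per run. AUROC is the tuning objective
because it is threshold-free — the percentile calibration downstream supplies
the threshold.

## PCAP estimation and cutoff calibration

PCAP_x is estimated by nested cross-validation (defaults: 10 outer × 10
inner stratified folds). Per outer fold, the inner CV yields per-fold
precision and recall at every integer percentile p ∈ [50, 99] of the sorted
validation probabilities (linear-interpolation percentile; samples at or
above the threshold are called +1). A percentile earns a vote from each
inner fold whose precision there reaches x%; the smallest percentile with
the most votes is the fold's cutoff P_i, and the mean recall at P_i across
inner folds (folds without positive validation samples excluded) is its
recall R_i. If no percentile earns any vote, the fold is flagged
"target precision unattainable", pinned at percentile 99, and contributes
R_i = 0 — an unattainable target rescues nothing. The PCAP_x estimate is
mean(R_i); the deployment cutoff is mean(P_i) rounded to the nearest grid
integer. Each outer-training set is refit whole and its P_i applied — as a
percentile of the outer-test fold's own probability distribution — to report
the precision actually achieved on unseen data.

Applying the percentile to the evaluation set's own distribution is the
literal reading of a percentile cutoff and keeps the rule scale-free across
datasets; the integer grid means the called set can differ from the exact
top-x% by one sample, so achieved precision on a fold of size ~n can sit one
call below the target (granularity ≈ 1/n_fold).

Model selection compares candidates by the *median* per-outer-fold PCAP
(robust to one lucky fold); ties go to the earlier candidate. F1 and AUROC
selection criteria run the same outer folds for comparison designs.

Inner folds re-run the entire pipeline — screening and RFE included — so the
calibration never sees a feature set chosen on its own validation samples.

## Confident prediction

One-sided deployment: samples at or above the deployment-cutoff percentile
of the new cohort's probabilities are called +1, the rest abstain. Two-sided
(for group comparisons): prob ≥ 1−c → +1, prob ∈ [0, c) → −1 (half-open:
prob = c abstains), the middle band abstains; c = 0.5 covers [0,1] and
abstains on nothing.

## DGEA reliability evaluation

Differential expression uses per-gene Welch t-tests on log2(value + 1)
(pseudocount configurable), significant at unadjusted p < 0.05 by default —
overlap-count designs compare like with like, so multiple-testing correction
is off by default (Benjamini–Hochberg available). Overlap percent is
measured relative to the reference list, which is stated per experiment.

The five-arm experiment splits labeled samples into 10 stratified folds:
8 training (Dataset1), 1 predicted (Dataset2), 1 "newly collected"
(Dataset3), rotated 10× and repeated (default 50 repeats). The reference
DEG list comes from a one-fold-sized class-ratio-preserving subsample of
Dataset1; arms are Dataset2 with true labels, Dataset2 with confident
predicted labels under PCAP_95 / PCAP_90 calibration (two-sided rule,
c = 0.25 by default), Dataset3 with true labels, and Dataset2 with permuted
labels. Overlap counts against the reference are averaged over rotations.
For controlled-accuracy experiments the model can be replaced by oracle
probabilities (1−e for true +1, e for −1, flipped across 0.5 with
probability e); at e = 0 the prediction arms equal the truth arm exactly.

The cutoff sweep takes per-fold held-out probabilities, forms groups by the
two-sided rule at c ∈ {0.05, …, 0.5}, drops the middle band, and scores the
percentage of the all-sample true-label DEG list recovered. Cells where a
group has < 2 samples are undefined and excluded from per-c medians; the
summary is the argmax-c and its median overlap.

## Synthetic data

The generator emulates the input structure end to end: log-normal expression
2^(b_g + Δ·[informative ∧ class +1] + N(0, σ)) with per-gene baselines
b_g ~ U(3, 10) on the log2 scale, per-sample library-scale factors
~ U(0.5, 2) (so per-sample normalization is consequential), a binary
variable with configurable minority fraction, and MCAR-masked metadata.
Defaults — 600 samples × 2000 genes, 50 informative genes at log2
fold-change 1.0, 25% minority, σ = 1.0, 10% missing — are the standing study
conditions for the calibration experiments. σ = 1.0 is a typical within-class
log2 dispersion for bulk expression; log2FC 1.0 across 50 genes gives a
strongly learnable but not separable signal, the regime where calibration
matters. The generator does not model count discreteness, batch effects,
gene–gene correlation, or platform transfer, so results on it say nothing
about those failure modes.

## Numerical choices and degenerate inputs

- Percentile definition: linear interpolation on sorted values, everywhere,
  including the brute-force oracles.
- Class-size ties in label encoding break lexicographically.
- Cutoff-vote ties select the smallest percentile.
- Tuning-score ties select the first draw.
- Candidate-score ties in model selection select the earlier candidate.
- Labels are remapped +1/−1 → 1/0 at the estimator boundary (gradient-boosted
  trees require classes starting at 0).
- Precision with zero calls is undefined (NaN) and never votes; recall with
  zero true positives is 0.
- All randomness flows from one root seed through `numpy.random.default_rng`,
  expanded deterministically per stage; the same seed reproduces every fold
  assignment, draw, and synthetic sample exactly.

## Problem sizes

The packaged experiments run at desk scale: calibration at the default
600 × 2000 conditions over 5 seeds with a 2-candidate grid (the rank-normalized
lasso with and without SMOTE, mirroring the RN / RN+SMOTE design columns),
dominance over 20 nested-CV seeds at 120 × 150, oracle-equivalence instances
at ≤ 60 samples × 30 genes, and DGEA arms at 160 × 120 with 20 repeats.

## Known limitations

- Binary variables only; multi-class rescue would need one-vs-rest wrapping.
- Selective prediction can select a biased subset: the confidently-predicted
  samples need not be representative, and conclusions drawn from them apply
  to that stratum.
- The achieved-precision guarantee is statistical, not per-cohort: a single
  small test fold can fall below x% even when calibration is correct on
  average.
- Percentile cutoffs assume the deployment cohort's probability distribution
  resembles validation; a frozen absolute-probability threshold is the safer
  choice under strong cohort shift (available via the calibration output).
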