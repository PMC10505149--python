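# Methods

This note records the modeling assumptions, parameter choices and
numerical conventions behind `tootrace`, and what the synthetic study
conditions do and do not demonstrate about real cohorts.

## The classification procedure

The pipeline treats tissue-of-origin inference as supervised multi-class
classification of samples × genes expression matrices. Three stages are
composed, and the composition — not any single stage — is the object of
study: per-sample normalization, per-class gene-panel selection, and a
standard classifier.

**Normalization is strictly per sample.** Both variants (L1 proportion
scaling; log2 with pseudocount 1e-6 followed by z-scoring against the
sample's own mean and standard deviation) use no statistics from other
samples. This is the less common convention — most expression workflows
standardize each gene across the cohort — and it is deliberate: it makes
the trained model applicable to a single new specimen, and to an external
cohort, with zero information flowing from training data into test-time
preprocessing. The z-score uses the population standard deviation
(divide by n); `tootrace.preprocess.SD_DDOF` switches to the n−1
convention if needed. Zero-sum and zero-variance samples raise errors
rather than emitting zeros, because silent zero vectors would poison
distance-based classifiers.

**Panel selection.** The primary selector fits one multinomial logistic
regression on all genes jointly (not per-class one-vs-rest fits) with an
L2 penalty of strength 1e-4 (inverse-regularization constant 10,000 —
nearly unpenalized, so coefficient magnitudes reflect discriminative
weight rather than shrinkage). Per class, genes are ranked by
|coefficient| and the top N kept; the panel is the deduplicated union in
class order, then rank order. Budgets quoted as a nominal total are
divided by 10 to give the per-class count (minimum 1), so the grid axis
stays a single list of integers across selectors. Ties in |coefficient|
or forest importance are broken by ascending gene id, which keeps
rankings reproducible across platforms. The forest selector uses 2000
bootstrapped Gini trees with a √N per-tree feature cap; the random
selector is the no-information baseline; a "none" selector (all genes)
is included because an almost-unpenalized logistic classifier is largely
insensitive to feature redundancy.

**Classifiers.** "Default parameters" are pinned explicitly so behavior
cannot drift with library versions: logistic regression (L2, C = 1,
lbfgs, iteration cap 5000), random forest (100 Gini trees, √N cap),
k-nearest neighbors with k = 5 (the classical choice of the RT-PCR TOO
literature; exposed as a parameter), and a one-vs-all RBF SVM with
C = 10,000. The SVM reports a softmax over one-vs-all decision values as
a probability surrogate — monotone in the decision scores but not
calibrated. For every classifier the predicted class is the argmax of
the (surrogate) probability vector, ties broken by class order, so the
argmax-equals-prediction invariant holds uniformly.

**Preprocessing order.** Models normalize the FULL gene vector first and
subset to the panel second. Normalizing after subsetting gives different
numbers (the within-sample mean/sd and the L1 denominator would depend
on the panel), so the order is part of the model contract; at prediction
time a matrix missing non-panel training genes is rejected with an error
explaining the within-sample-statistics dependency.

## Cross-validation and the grid

Folds are stratified (per-fold class proportions within one sample of
global ones) and deterministic given a seed. A class with fewer than k
samples raises; the leave-one-out limit k = n is supported as a special
case. Gene selection is re-run inside every fold on the k−1 training
folds only — the design that the permuted-label sentinel checks: with
labels shuffled, no combination may beat chance beyond binomial noise,
which fails immediately if selection ever sees held-out labels.

Held-out predictions are pooled across folds for the headline accuracy
and per-class metrics (identical to averaging per-fold accuracies for
equal fold sizes and better defined for unequal ones); per-fold
accuracies are also reported. Repeated CV is not performed; a single
stratified repetition per seed keeps results one-seed-one-number, and
seed sweeps are the caller's loop.

Per-class metrics are one-vs-rest: precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP); zero-denominator cases report 0.0
with an explicit `*_defined = False` flag rather than NaN. Confusion
matrices carry raw counts plus row-normalized fractions; empty true-class
rows are all-zero and flagged.

Each grid cell's randomness is seeded by a stable hash of the master
seed and the combination key, so the grid is reproducible cell-by-cell
and its output is byte-identical regardless of evaluation order. A
failing cell records its error in the table and the grid continues.

The class × top-gene marker summary computes log2(mean raw expression
+ 1e-12) — log of the class mean, not mean of logs; the caption-level
ambiguity between the two readings is resolved in favor of log-of-mean,
and the pseudocount is deliberately the display-scale 1e-12 rather than
the preprocessing 1e-6.

## Cross-cohort protocol

Harmonization restricts both cohorts to the ordered intersection of
their gene ids (training-matrix order; ids are opaque strings — no
symbol/Ensembl mapping). Selection and training are re-run AFTER
intersection, so the final panel is provably a subset of the shared gene
space. No correction for expression-unit or platform differences is
applied beyond the per-sample normalization; this is faithful to the
workflow being studied and is the main known limitation — a strong
per-gene shift that happens to land on panel genes degrades transfer
accuracy, as the synthetic experiments show.

## The synthetic cohort generator

The generator is multiplicative lognormal throughout: per-gene baseline
means are drawn lognormally (ln-mean ln 10, ln-sd 1.5 — a heavy-tailed,
TPM-like abundance distribution spanning several orders of magnitude);
each class elevates its planted marker genes by a known fold-change;
each sample is scaled by a unit-mean lognormal library-size factor; each
value carries unit-mean lognormal noise. Because every factor has unit
mean, the expected value of gene g in class c is exactly
`baseline_g × fold^(g is a marker of c)`, and tests compare sample means
against this analytic law. A lognormal (rather than count) model was
chosen because the pipeline consumes continuous TPM-like values and the
log2 + z-score transform is exactly linear on lognormal data.

Defaults define the study conditions: 4 classes × 60 samples, 500 genes,
5 markers per class at 8-fold elevation, library-size CV 0.3, noise
dispersion 0.5 (ln-scale sd, i.e. most values within ±65% of their
mean — a realistic bulk-RNA-seq scale of biological plus technical
variation). Class sizes accept arbitrary imbalance (the test suite
exercises a 36-to-1102 spread). "Adjacent" classes can share a stated
number of markers, elevated in both; this reproduces the
liver/bile-duct style of confusable pair, and the confusion matrix of a
cohort sharing 4 of 5 markers concentrates each class's errors on its
partner.

External cohorts reuse the class/marker law with new samples, apply an
independent per-gene multiplicative shift of ln-sd 2.0, and drop exactly
⌈gene_loss_fraction × N⌉ genes, never planted markers. The shift
magnitude was chosen to emulate transfer between cohorts whose
expression-calling pipelines (or even units) differ: at ln-sd 1 the
shift is negligible against 8-fold markers and transfer is lossless,
which no real cross-cohort application achieves, while ln-sd 2 produces
the characteristic ordering chance < external accuracy < same-cohort CV
accuracy. Because the shift is random relative to the panel, individual
seeds vary widely (some transfers are nearly lossless); conclusions
should be drawn from seed sweeps, not single draws.

All randomness flows from one master seed through named streams
(baseline, markers, cohort, external, batch, gene-loss), so adding a new
random step never perturbs existing fixtures.

**What passing tests do not show.** The generator has independent genes
(no pathway covariance), multiplicative noise only (no dropout, no
batch structure within a cohort), and markers that are strictly
elevated (no down-regulated markers). Results on it demonstrate the
correctness and leakage-safety of the machinery — not the accuracy the
workflow would reach on real tumor cohorts, which depends on biology the
generator does not model.

## Problem sizes

Tests and the acceptance script run the default 240 × 500 cohort for
selector and CV properties, a 45-sample × 1000-gene miniature cohort for
the 120-cell grid (with 50-tree forests standing in for the 2000-tree
default, which changes runtime but not the grid mechanics), and 3–5
replicate seeds for statistical properties. These sizes were chosen so
the full suite re-runs in minutes while keeping every class far enough
above the fold count for stratification.
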