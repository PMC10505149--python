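# tootrace

Tumor **tissue-of-origin (TOO)** classification from bulk RNA-seq
expression profiles. Carcinoma of unknown primary (CUP) is metastatic
cancer whose originating tissue cannot be identified by conventional
pathology; therapy targeting the original tissue improves prognosis, so
an accurate computational TOO call from an expression profile is
clinically valuable. `tootrace` implements the full machine-learning
workflow for this problem — per-sample normalization, per-class
gene-panel selection, classifier training, leakage-safe cross-validated
benchmarking of every method combination, and application of a trained
model to an external cohort after gene-space harmonization — together
with a planted-marker synthetic cohort generator so every stage is
testable without any data download.

It is written for computational biologists benchmarking TOO pipelines on
TCGA/ICGC-style cohorts (gene-by-sample TPM matrices with one cancer-type
label per sample) and for anyone who needs a leakage-safe multi-class
expression classifier with per-class metrics.

## The method

Given an M × N matrix of non-negative TPM-like values (M samples, N
genes) with one class label per sample:

1. **Per-sample normalization** (both variants are strictly within-sample,
   so a lone clinical specimen can be scored with no cohort statistics):
   - *L1 proportion scaling*: `G = g / Σᵢ gᵢ` over each sample's genes;
   - *log2 + within-sample standardization*: `x = log2(g + 1e-6)`, then
     `z = (x − u)/s` with `u`, `s` the mean and (population) standard
     deviation of that sample's log-values.
2. **Per-class panel selection**: one multinomial logistic regression
   (L2 penalty, strength 1e-4, i.e. C = 10,000) is fit on all genes; for
   each class the genes are ranked by |coefficient| and the top N per
   class are kept; the deduplicated union across classes is the panel.
   Forest-importance ranking (2000 Gini trees, √N feature cap) and a
   uniform-random baseline provide the comparison selectors. Nominal
   total budgets are divided by 10 to give the per-class count for the
   logistic selector.
3. **Classification** over the panel with logistic regression, random
   forest, k-nearest neighbors (k = 5), or a one-vs-all RBF SVM
   (C = 10,000).
4. **Benchmarking**: stratified 10-fold cross-validation in which panel
   selection is re-run inside each fold on the training folds only;
   the full preprocessing × selector × budget × classifier grid is
   evaluated and reported with pooled accuracy, per-class one-vs-rest
   precision / recall / specificity, and row-normalized confusion
   matrices.
5. **Cross-cohort transfer**: both cohorts are restricted to their gene-id
   intersection, selection and training are re-run on the restricted
   training cohort, and the external cohort is scored per sample.

## Worked example

```python
import numpy as np
from tootrace import (Combo, SyntheticConfig, cross_validate, generate_cohort,
                      generate_external_cohort, cross_cohort_fit,
                      log2_standardize, select_by_logistic, marker_recovery)

cohort, truth = generate_cohort(SyntheticConfig(seed=1))
print(f"cohort: {cohort.n_samples} samples x {cohort.n_genes} genes, "
      f"classes {cohort.class_names}")

panel = select_by_logistic(log2_standardize(cohort.X), cohort.y, n_per_class=5)
print(f"panel: {len(panel.combined_panel)} genes, "
      f"marker recovery {marker_recovery(truth, panel.combined_panel):.2f}")

cv = cross_validate(cohort.X, cohort.y, Combo("log2std", "logistic", 50, "lr"),
                    k=10, seed=1)
print(f"10-fold CV accuracy: {100 * cv.accuracy:.2f}%")

ext_X, ext_y = generate_external_cohort(SyntheticConfig(seed=1), truth)
model, report, pair = cross_cohort_fit(cohort.X, cohort.y, ext_X, budget=5, seed=1)
acc = np.mean(np.array(report.predicted) == ext_y.to_numpy())
print(f"external cohort ({len(pair.shared_genes)} shared genes): "
      f"accuracy {100 * acc:.2f}%")
```

Output:

```
cohort: 240 samples x 500 genes, classes ['C00', 'C01', 'C02', 'C03']
panel: 20 genes, marker recovery 1.00
10-fold CV accuracy: 100.00%
external cohort (400 shared genes): accuracy 58.75%
```

The generator plants 5 marker genes per class at 8-fold elevation; the
coefficient-ranked selector recovers all 20 of them, the winning
combination (log2 + z-score, logistic selection, logistic classification)
classifies the separable cohort perfectly under 10-fold CV, and accuracy
drops — while staying far above the 25% chance level — on an external
cohort with a per-gene platform shift and 20% of genes missing. That
ordering (same-cohort CV > external > chance) is the qualitative
signature of real cross-cohort transfer.

The same workflow is available from the shell:

```bash
tootrace simulate --seed 1 --out-prefix fixtures/cohort --external
tootrace cv --preprocess log2std --select logistic --genes 50 --clf lr \
    --k 10 --seed 1 --in fixtures/cohort.matrix.tsv \
    --labels fixtures/cohort.labels.tsv --out-prefix results/cv
tootrace xcohort --train fixtures/cohort.matrix.tsv \
    --train-labels fixtures/cohort.labels.tsv \
    --test fixtures/cohort.external.matrix.tsv \
    --genes-per-class 5 --seed 1 --out results/external.tsv
```

## Layout

- `tootrace.io` — expression tables, label files, gene lists, TCGA-style
  barcode parsing, label merging (e.g. COAD+READ→COADREAD).
- `tootrace.preprocess` — the two per-sample normalizations.
- `tootrace.select` — panel selectors and the per-class union construction.
- `tootrace.model` — `TissueOfOriginClassifier` (scikit-learn estimator)
  with directory serialization.
- `tootrace.evaluate` — stratified CV, metrics, confusion matrices, the
  combination grid, the class-mean marker summary.
- `tootrace.cohort` — gene-space harmonization and cross-cohort fitting.
- `tootrace.synthetic` — the planted-marker cohort generator.
- `tootrace.cli` — the `tootrace` command.

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
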