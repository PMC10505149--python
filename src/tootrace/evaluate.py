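"""Leakage-safe cross-validated benchmarking of method combinations.

The central loop is stratified k-fold cross-validation in which gene
selection is re-run INSIDE each fold on the k-1 training folds only —
selecting features on the full cohort before splitting leaks label
information and inflates accuracy, which is why the leakage sentinel
(label-permuted data must score at chance) is a first-class test here.

``run_grid`` evaluates the full Cartesian product of preprocessing x
selection method x nominal gene number x classifier, the benchmarking
design used to find the winning combination (log2 + within-sample
standardization, per-class logistic selection, logistic classification).

Metrics are one-vs-rest per class: precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP); confusion matrices carry raw counts
and row-normalized fractions (each non-empty true-class row sums to 1).
Held-out predictions are pooled over folds; per-fold accuracies are also
reported.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from ._seeds import derive_seed
from .model import TissueOfOriginClassifier
from .preprocess import apply_preprocessing
from .select import SelectionResult, make_selector, resolve_gene_budget

#: pseudocount for the class-mean marker heatmap (distinct from the
#: preprocessing pseudocount on purpose)
HEATMAP_PSEUDOCOUNT = 1e-12


# ----------------------------------------------------------------------
# fold assignment
# ----------------------------------------------------------------------
@dataclass
class FoldAssignment:
    """A stratified partition of samples into k folds."""

    k: int
    fold_of: np.ndarray  # fold index per sample, shape (n_samples,)
    seed: int | None

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)


def stratified_kfold(labels, k: int, seed: int | None = 0) -> FoldAssignment:
    """Deterministic stratified fold assignment.

    Folds partition the samples; per-fold class proportions are within
    one sample of the global proportions. A class with fewer than k
    samples raises (it could not appear in every fold), except in the
    leave-one-out limit k == n_samples, where each sample is its own
    single-element fold and stratification is moot.
    """
    y = np.asarray(labels)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    fold_of = np.empty(n, dtype=int)
    if k == n:  # leave-one-out special case
        fold_of[:] = np.arange(n)
        return FoldAssignment(k=k, fold_of=fold_of, seed=seed)
    classes, counts = np.unique(y, return_counts=True)
    too_small = classes[counts < k]
    if too_small.size:
        raise ValueError(
            f"class {too_small[0]!r} has fewer than k={k} samples; "
            "reduce k or drop the class"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        fold_of[test_idx] = fold
    return FoldAssignment(k=k, fold_of=fold_of, seed=seed)


# ----------------------------------------------------------------------
# per-class metrics and confusion matrices
# ----------------------------------------------------------------------
@dataclass
class ConfusionResult:
    """Confusion counts and row-normalized fractions (rows = true class)."""

    classes: list[str]
    counts: pd.DataFrame
    fractions: pd.DataFrame
    row_defined: pd.Series  # False where the true class never occurs


def confusion(true, pred, classes: Sequence[str] | None = None) -> ConfusionResult:
    true = np.asarray(true, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(true) != len(pred):
        raise ValueError("true and pred have different lengths")
    if classes is None:
        classes = sorted(set(true) | set(pred))
    classes = [str(c) for c in classes]
    unknown = set(map(str, pred)) - set(classes)
    if unknown:
        raise ValueError(f"predicted labels outside the class list: {unknown}")
    counts = _sk_confusion(true.astype(str), pred.astype(str), labels=classes)
    counts_df = pd.DataFrame(counts, index=classes, columns=classes)
    counts_df.index.name = "true"
    counts_df.columns.name = "predicted"
    row_sums = counts_df.sum(axis=1)
    defined = row_sums > 0
    fractions = counts_df.div(row_sums.where(defined, 1), axis=0).astype(float)
    fractions[~defined] = 0.0
    return ConfusionResult(
        classes=classes,
        counts=counts_df,
        fractions=fractions,
        row_defined=defined.rename("row_defined"),
    )


def per_class_metrics(true, pred, classes: Sequence[str] | None = None) -> pd.DataFrame:
    """One-vs-rest precision, recall and specificity per class.

    Undefined ratios (zero denominator) are reported as 0.0 with the
    corresponding ``*_defined`` flag set to False.
    """
    conf = confusion(true, pred, classes)
    counts = conf.counts.to_numpy(dtype=float)
    total = counts.sum()
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn

    def _safe(num, den):
        den = np.asarray(den, dtype=float)
        defined = den > 0
        out = np.zeros_like(den)
        out[defined] = num[defined] / den[defined]
        return out, defined

    precision, p_def = _safe(tp, tp + fp)
    recall, r_def = _safe(tp, tp + fn)
    specificity, s_def = _safe(tn, tn + fp)
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "precision_defined": p_def,
            "recall_defined": r_def,
            "specificity_defined": s_def,
            "support": counts.sum(axis=1).astype(int),
        },
        index=pd.Index(conf.classes, name="class"),
    )


def accuracy_score_pooled(true, pred) -> float:
    true = np.asarray(true, dtype=object)
    pred = np.asarray(pred, dtype=object)
    if len(true) != len(pred):
        raise ValueError("true and pred have different lengths")
    return float(np.mean(true.astype(str) == pred.astype(str)))


# ----------------------------------------------------------------------
# cross-validation of one combination
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class Combo:
    """One grid cell: preprocessing, selector, nominal gene number, classifier."""

    preprocess: str | None
    selector: str
    n_genes: int | None  # nominal total; None only with selector='none'
    classifier: str

    def key(self) -> str:
        return f"{self.preprocess}|{self.selector}|{self.n_genes}|{self.classifier}"


@dataclass
class CVResult:
    """Pooled held-out predictions and metrics for one combination."""

    combo: Combo
    k: int
    seed: int | None
    folds: FoldAssignment
    predictions: pd.DataFrame  # sample_id, fold, true, predicted
    accuracy: float
    per_fold_accuracy: list[float]
    per_class: pd.DataFrame
    confusion: ConfusionResult
    selected_panels: list[list[str]]


def cross_validate(
    X: pd.DataFrame,
    y,
    combo: Combo,
    k: int = 10,
    seed: int | None = 0,
    selector_params: Mapping | None = None,
    classifier_params: Mapping | None = None,
) -> CVResult:
    """Stratified k-fold CV with in-fold gene selection.

    Per fold: preprocess the training rows, run the combination's gene
    selection on those rows ONLY, train the classifier on the resulting
    panel, then score the held-out fold. Held-out predictions are pooled
    across folds for the headline accuracy and per-class metrics.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=object), index=X.index)
    classes = sorted(map(str, y.unique()))
    folds = stratified_kfold(y.to_numpy(), k=k, seed=seed)
    selector_params = dict(selector_params or {})
    classifier_params = dict(classifier_params or {})

    records = []
    panels: list[list[str]] = []
    per_fold_acc: list[float] = []
    for fold in range(folds.k):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        X_tr, y_tr = X.iloc[tr], y.iloc[tr]
        X_te, y_te = X.iloc[te], y.iloc[te]
        fold_seed = derive_seed(seed or 0, f"fold-{fold}")

        panel = _select_panel(
            X_tr, y_tr, combo, seed=fold_seed, selector_params=selector_params
        )
        model = TissueOfOriginClassifier(
            preprocess=combo.preprocess,
            classifier=combo.classifier,
            panel=panel,
            random_state=fold_seed,
            **classifier_params,
        ).fit(X_tr, y_tr)
        pred = model.predict(X_te)
        per_fold_acc.append(accuracy_score_pooled(y_te, pred))
        panels.append(list(panel) if panel is not None else list(X.columns.astype(str)))
        for sid, t, p in zip(X_te.index, y_te, pred):
            records.append((str(sid), fold, str(t), str(p)))

    predictions = pd.DataFrame(
        records, columns=["sample_id", "fold", "true", "predicted"]
    )
    acc = accuracy_score_pooled(predictions["true"], predictions["predicted"])
    metrics = per_class_metrics(predictions["true"], predictions["predicted"], classes)
    conf = confusion(predictions["true"], predictions["predicted"], classes)
    return CVResult(
        combo=combo,
        k=k,
        seed=seed,
        folds=folds,
        predictions=predictions,
        accuracy=acc,
        per_fold_accuracy=per_fold_acc,
        per_class=metrics,
        confusion=conf,
        selected_panels=panels,
    )


def _select_panel(
    X_tr: pd.DataFrame,
    y_tr: pd.Series,
    combo: Combo,
    seed: int | None,
    selector_params: Mapping,
) -> list[str] | None:
    """Run the combo's selection on training data; None = all genes."""
    if combo.selector == "none":
        return None
    budget = resolve_gene_budget(combo.n_genes, combo.selector)
    selector = make_selector(combo.selector, budget=budget, seed=seed, **selector_params)
    prepped = apply_preprocessing(X_tr, combo.preprocess)
    selector.fit(pd.DataFrame(prepped, index=X_tr.index, columns=X_tr.columns), y_tr)
    return selector.panel_


# ----------------------------------------------------------------------
# the combination grid
# ----------------------------------------------------------------------
@dataclass
class GridResult:
    """Long-format table of per-combination CV metrics, best first."""

    table: pd.DataFrame
    cv_results: dict[str, CVResult] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def expand_grid(
    preprocess_axis: Sequence[str | None],
    selector_axis: Sequence[str],
    gene_axis: Sequence[int],
    classifier_axis: Sequence[str],
) -> list[Combo]:
    """Cartesian product of the axes; the 'none' selector ignores the
    gene axis and contributes one combo per (preprocess, classifier)."""
    combos: list[Combo] = []
    for prep, sel, clf in itertools.product(
        preprocess_axis, selector_axis, classifier_axis
    ):
        if sel == "none":
            combos.append(Combo(prep, sel, None, clf))
        else:
            combos.extend(Combo(prep, sel, int(g), clf) for g in gene_axis)
    return combos


def run_grid(
    X: pd.DataFrame,
    y,
    preprocess_axis: Sequence[str | None] = ("l1", "log2std"),
    selector_axis: Sequence[str] = ("rf", "logistic", "random"),
    gene_axis: Sequence[int] = (50, 100, 200, 400, 800),
    classifier_axis: Sequence[str] = ("rf", "lr", "knn", "svm"),
    k: int = 10,
    seed: int | None = 0,
    selector_params: Mapping | None = None,
    classifier_params: Mapping | None = None,
    keep_cv_results: bool = False,
) -> GridResult:
    """Cross-validate every combination of the four axes.

    Each combo's randomness is seeded by a stable hash of the master
    seed and the combo key, so results are identical regardless of the
    order combos are evaluated in. A failing combo is recorded in its
    row (``error`` column) and the grid continues. Rows are sorted by
    non-increasing accuracy, with the combo key as a deterministic
    tie-break.
    """
    combos = expand_grid(preprocess_axis, selector_axis, gene_axis, classifier_axis)
    rows = []
    cv_results: dict[str, CVResult] = {}
    for combo in combos:
        combo_seed = derive_seed(seed or 0, f"combo|{combo.key()}")
        row = {
            "preprocess": combo.preprocess,
            "selector": combo.selector,
            "genes": combo.n_genes if combo.n_genes is not None else "all",
            "classifier": combo.classifier,
        }
        try:
            res = cross_validate(
                X,
                y,
                combo,
                k=k,
                seed=combo_seed,
                selector_params=selector_params,
                classifier_params=classifier_params,
            )
        except Exception as exc:  # a combo failure must not kill the grid
            row.update(
                accuracy=np.nan,
                macro_precision=np.nan,
                macro_recall=np.nan,
                macro_specificity=np.nan,
                error=f"{type(exc).__name__}: {exc}",
            )
        else:
            row.update(
                accuracy=res.accuracy,
                macro_precision=float(res.per_class["precision"].mean()),
                macro_recall=float(res.per_class["recall"].mean()),
                macro_specificity=float(res.per_class["specificity"].mean()),
                error="",
            )
            if keep_cv_results:
                cv_results[combo.key()] = res
        rows.append(row)
    table = pd.DataFrame(rows)
    key = table.apply(
        lambda r: f"{r['preprocess']}|{r['selector']}|{r['genes']}|{r['classifier']}",
        axis=1,
    )
    table = (
        table.assign(_key=key)
        .sort_values(["accuracy", "_key"], ascending=[False, True], na_position="last")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return GridResult(table=table, cv_results=cv_results)


# ----------------------------------------------------------------------
# marker heatmap summary
# ----------------------------------------------------------------------
def marker_expression_summary(
    X: pd.DataFrame,
    y,
    top_gene_per_class: Mapping[str, str],
    pseudocount: float = HEATMAP_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Class x gene matrix of log2(mean raw expression + 1e-12).

    One row per class, one column per class's top selected gene (columns
    follow the class order of their source class), the matrix behind the
    marker heatmap: on-diagonal entries should dominate their row when
    selection found genuinely class-specific genes. The mean is taken on
    RAW values and then logged.
    """
    X = pd.DataFrame(X)
    y = pd.Series(np.asarray(y, dtype=object), index=X.index)
    classes = list(top_gene_per_class)
    genes = [top_gene_per_class[c] for c in classes]
    missing = [g for g in genes if g not in X.columns]
    if missing:
        raise ValueError(f"genes absent from matrix: {missing}")
    out = np.empty((len(classes), len(genes)))
    for i, cls in enumerate(classes):
        members = y == cls
        if not members.any():
            raise ValueError(f"class {cls!r} has no samples")
        means = X.loc[members.to_numpy(), genes].mean(axis=0).to_numpy(dtype=float)
        out[i] = np.log2(means + pseudocount)
    return pd.DataFrame(
        out, index=pd.Index(classes, name="class"), columns=pd.Index(genes, name="gene")
    )
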