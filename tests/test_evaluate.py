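"""Stratified CV, metric oracles, the combination grid, marker summary.

The metric oracle is an exhaustive per-class TP/FP/FN/TN count done with
plain loops, entirely independent of the package's vectorized path.
"""

import numpy as np
import pandas as pd
import pytest

from tootrace import (
    Combo,
    SyntheticConfig,
    confusion,
    cross_validate,
    generate_cohort,
    marker_expression_summary,
    per_class_metrics,
    run_grid,
    stratified_kfold,
)
from tootrace._seeds import derive_seed


def counting_oracle(true, pred, classes):
    """Brute-force one-vs-rest contingency per class."""
    out = {}
    for c in classes:
        tp = sum(1 for t, p in zip(true, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(true, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(true, pred) if t == c and p != c)
        tn = sum(1 for t, p in zip(true, pred) if t != c and p != c)
        out[c] = {
            "precision": tp / (tp + fp) if tp + fp else 0.0,
            "recall": tp / (tp + fn) if tp + fn else 0.0,
            "specificity": tn / (tn + fp) if tn + fp else 0.0,
        }
    return out


class TestStratifiedKFold:
    def test_balanced_two_class_split_is_exact(self):
        y = ["A"] * 5 + ["B"] * 5
        folds = stratified_kfold(y, k=5, seed=0)
        for f in range(5):
            test_labels = [y[i] for i in folds.test_indices(f)]
            assert sorted(test_labels) == ["A", "B"]

    def test_folds_partition_the_samples(self):
        rng = np.random.default_rng(0)
        y = rng.choice(["A", "B", "C"], size=47, p=[0.5, 0.3, 0.2])
        folds = stratified_kfold(y, k=4, seed=1)
        all_idx = np.concatenate([folds.test_indices(f) for f in range(4)])
        assert sorted(all_idx) == list(range(47))

    def test_small_class_rejected_naming_it(self):
        y = ["A"] * 20 + ["RARE"] * 3
        with pytest.raises(ValueError, match="RARE"):
            stratified_kfold(y, k=10, seed=0)

    def test_leave_one_out_limit_runs(self):
        y = ["A", "B", "C"] * 4
        folds = stratified_kfold(y, k=12, seed=0)
        assert folds.k == 12
        assert all(len(folds.test_indices(f)) == 1 for f in range(12))

    def test_deterministic_given_seed(self):
        y = ["A"] * 12 + ["B"] * 8
        a = stratified_kfold(y, k=4, seed=9)
        b = stratified_kfold(y, k=4, seed=9)
        np.testing.assert_array_equal(a.fold_of, b.fold_of)


class TestMetrics:
    def test_worked_example(self):
        metrics = per_class_metrics(
            ["A", "A", "B", "B"], ["A", "B", "B", "B"], classes=["A", "B"]
        )
        assert metrics.loc["A", "precision"] == 1.0
        assert metrics.loc["A", "recall"] == 0.5
        assert metrics.loc["A", "specificity"] == 1.0
        assert metrics.loc["B", "precision"] == pytest.approx(2 / 3)
        assert metrics.loc["B", "recall"] == 1.0
        assert metrics.loc["B", "specificity"] == 0.5

    def test_perfect_prediction_scores_one_everywhere(self):
        y = ["A", "B", "C", "A"]
        metrics = per_class_metrics(y, y)
        assert (metrics[["precision", "recall", "specificity"]] == 1.0).all().all()

    def test_absent_class_flagged_zero(self):
        metrics = per_class_metrics(
            ["A", "A"], ["A", "A"], classes=["A", "GHOST"]
        )
        row = metrics.loc["GHOST"]
        assert row["precision"] == 0.0 and not row["precision_defined"]
        assert row["recall"] == 0.0 and not row["recall_defined"]
        # TN/(TN+FP) is defined for a never-seen class: everything is a TN
        assert row["specificity"] == 1.0 and row["specificity_defined"]

    def test_agrees_with_counting_oracle_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n_classes = rng.integers(2, 9)
            classes = [f"K{c}" for c in range(n_classes)]
            n = int(rng.integers(1, 60))
            true = rng.choice(classes, size=n)
            pred = rng.choice(classes, size=n)
            metrics = per_class_metrics(true, pred, classes)
            oracle = counting_oracle(list(true), list(pred), classes)
            for c in classes:
                for m in ("precision", "recall", "specificity"):
                    assert metrics.loc[c, m] == pytest.approx(oracle[c][m])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            per_class_metrics(["A"], ["A", "B"])


class TestConfusion:
    def test_perfect_prediction_is_identity(self):
        y = ["A", "B", "C"]
        conf = confusion(y, y)
        np.testing.assert_array_equal(conf.fractions.to_numpy(), np.eye(3))

    def test_rows_with_true_samples_sum_to_one(self):
        rng = np.random.default_rng(1)
        true = rng.choice(["A", "B", "C"], size=50)
        pred = rng.choice(["A", "B", "C"], size=50)
        conf = confusion(true, pred)
        sums = conf.fractions.sum(axis=1)
        assert np.allclose(sums[conf.row_defined], 1.0, atol=1e-9)

    def test_split_row_fractions(self):
        conf = confusion(
            ["A", "A", "A", "A"], ["A", "A", "A", "B"], classes=["A", "B"]
        )
        np.testing.assert_allclose(conf.fractions.loc["A"], [0.75, 0.25])

    def test_empty_true_row_flagged_all_zero(self):
        conf = confusion(["A", "A"], ["A", "B"], classes=["A", "B"])
        assert not conf.row_defined["B"]
        assert (conf.fractions.loc["B"] == 0).all()

    def test_accuracy_equals_normalized_trace(self):
        rng = np.random.default_rng(2)
        true = rng.choice(["A", "B", "C"], size=80)
        pred = rng.choice(["A", "B", "C"], size=80)
        conf = confusion(true, pred)
        acc = np.mean(true == pred)
        assert np.trace(conf.counts.to_numpy()) / 80 == pytest.approx(acc)


class TestCrossValidate:
    def test_best_combo_on_separable_fixture(self, default_cohort):
        ds, _ = default_cohort
        combo = Combo("log2std", "logistic", 50, "lr")
        res = cross_validate(ds.X, ds.y, combo, k=10, seed=1)
        assert res.accuracy >= 0.98
        # pooled accuracy equals the confusion-trace identity
        trace = np.trace(res.confusion.counts.to_numpy())
        assert trace / len(ds.y) == pytest.approx(res.accuracy)

    def test_in_fold_selection_panels_differ_and_are_recorded(self, default_cohort):
        ds, _ = default_cohort
        combo = Combo("log2std", "random", 30, "lr")
        res = cross_validate(ds.X, ds.y, combo, k=5, seed=1)
        assert len(res.selected_panels) == 5
        assert len({tuple(p) for p in res.selected_panels}) > 1

    def test_leave_one_out_degenerate_k(self):
        ds, _ = generate_cohort(
            SyntheticConfig(n_classes=3, samples_per_class=4, n_genes=30,
                            markers_per_class=2, seed=5)
        )
        combo = Combo("log2std", "none", None, "knn")
        res = cross_validate(ds.X, ds.y, combo, k=12, seed=0)
        assert len(res.per_fold_accuracy) == 12
        assert len(res.predictions) == 12

    def test_permuted_labels_score_at_chance(self, default_cohort):
        """Leakage sentinel: with labels shuffled, in-fold selection must
        not beat chance (within 3 binomial sd of 1/4)."""
        ds, _ = default_cohort
        rng = np.random.default_rng(1)
        yperm = rng.permutation(ds.y.to_numpy())
        combo = Combo("log2std", "logistic", 50, "lr")
        res = cross_validate(ds.X, yperm, combo, k=10, seed=1)
        n = len(yperm)
        band = 3 * np.sqrt(0.25 * 0.75 / n)
        assert abs(res.accuracy - 0.25) <= band


class TestGrid:
    def test_one_cell_grid_equals_direct_cross_validation(self, mini_grid_cohort):
        ds, _ = mini_grid_cohort
        grid = run_grid(
            ds.X, ds.y,
            preprocess_axis=("log2std",), selector_axis=("random",),
            gene_axis=(20,), classifier_axis=("lr",), k=3, seed=4,
        )
        assert len(grid.table) == 1
        combo = Combo("log2std", "random", 20, "lr")
        direct = cross_validate(
            ds.X, ds.y, combo, k=3, seed=derive_seed(4, f"combo|{combo.key()}")
        )
        assert grid.table.loc[0, "accuracy"] == pytest.approx(direct.accuracy)

    def test_rows_sorted_by_nonincreasing_accuracy(self, mini_grid_cohort):
        ds, _ = mini_grid_cohort
        grid = run_grid(
            ds.X, ds.y,
            preprocess_axis=("l1", "log2std"), selector_axis=("random", "none"),
            gene_axis=(10,), classifier_axis=("lr", "knn"), k=3, seed=0,
        )
        acc = grid.table["accuracy"].to_numpy()
        assert np.all(np.diff(acc) <= 1e-12)

    def test_failed_combo_recorded_without_killing_the_grid(self, mini_grid_cohort):
        ds, _ = mini_grid_cohort
        grid = run_grid(
            ds.X, ds.y,
            preprocess_axis=("log2std",), selector_axis=("random",),
            gene_axis=(10, 10_000), classifier_axis=("lr",), k=3, seed=0,
        )
        assert len(grid.table) == 2
        failed = grid.table[grid.table["error"] != ""]
        assert len(failed) == 1 and np.isnan(failed["accuracy"]).all()

    def test_none_selector_collapses_gene_axis(self, mini_grid_cohort):
        ds, _ = mini_grid_cohort
        grid = run_grid(
            ds.X, ds.y,
            preprocess_axis=("log2std",), selector_axis=("none",),
            gene_axis=(10, 20, 30), classifier_axis=("lr",), k=3, seed=0,
        )
        assert len(grid.table) == 1
        assert grid.table.loc[0, "genes"] == "all"


class TestMarkerSummary:
    def test_planted_markers_dominate_their_row_on_flat_baseline(self):
        """With a flat baseline the 8-fold markers must dominate their
        row strictly; heterogeneous baselines only guarantee this on
        average (a low-baseline marker can sit below another class's
        abundant gene in raw expression)."""
        rng = np.random.default_rng(0)
        classes = ["A", "B", "C"]
        genes = [f"g{j}" for j in range(9)]
        markers = {"A": "g0", "B": "g1", "C": "g2"}
        rows, labels = [], []
        for cls in classes:
            means = np.full(9, 10.0)
            means[genes.index(markers[cls])] *= 8.0
            rows.append(means * rng.lognormal(-0.125, 0.5, size=(20, 9)))
            labels += [cls] * 20
        X = pd.DataFrame(
            np.vstack(rows), columns=genes,
            index=[f"s{i}" for i in range(60)],
        )
        summary = marker_expression_summary(X, pd.Series(labels, index=X.index), markers)
        values = summary.to_numpy()
        for i in range(len(values)):
            off = np.delete(values[i], i)
            assert values[i, i] > off.max()

    def test_diagonal_dominates_on_average_on_default_cohort(self, default_cohort):
        ds, truth = default_cohort
        top = {cls: truth.markers[cls][0] for cls in truth.class_names}
        summary = marker_expression_summary(ds.X, ds.y, top)
        values = summary.to_numpy()
        diag = np.diag(values)
        off = values[~np.eye(len(values), dtype=bool)]
        assert diag.mean() > off.mean()

    def test_single_class_single_gene_scalar(self):
        X = pd.DataFrame({"g1": [2.0, 6.0]}, index=["s1", "s2"])
        y = pd.Series(["A", "A"], index=X.index)
        out = marker_expression_summary(X, y, {"A": "g1"})
        assert out.loc["A", "g1"] == pytest.approx(np.log2(4.0 + 1e-12))

    def test_zero_mean_hits_pseudocount_floor(self):
        X = pd.DataFrame({"g1": [0.0, 0.0]}, index=["s1", "s2"])
        y = pd.Series(["A", "A"], index=X.index)
        out = marker_expression_summary(X, y, {"A": "g1"})
        assert out.loc["A", "g1"] == pytest.approx(np.log2(1e-12))

    def test_missing_gene_rejected(self, tiny_matrix):
        y = pd.Series(["A", "A", "B", "B"], index=tiny_matrix.index)
        with pytest.raises(ValueError, match="gNOPE"):
            marker_expression_summary(tiny_matrix, y, {"A": "gNOPE"})
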