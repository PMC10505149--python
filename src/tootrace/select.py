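"""Gene-panel selection: multinomial-coefficient ranking, forest importance,
and a random baseline.

The central construction is the per-class union panel: one multinomial
logistic regression (L2, weak regularization) is fit on all genes, the
genes are ranked per class by absolute coefficient, the top N per class
are kept, and the deduplicated union across classes becomes the panel
used as classifier features. Forest-importance and uniform-random
selection produce a single global ranking instead.

Budgets are quoted as a nominal total gene number; for the per-class
logistic selector the nominal total is divided by 10 to give the
per-class count (so a nominal budget of 800 on a 32-class cohort means
80 genes per class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

#: the paper-grid convention: nominal total / 10 = per-class count
LOGISTIC_BUDGET_DIVISOR = 10
#: default L2 regularization strength for the selection model (C = 1/strength)
DEFAULT_L2_STRENGTH = 1e-4
#: default number of trees for forest-importance selection
DEFAULT_SELECTOR_TREES = 2000


@dataclass
class SelectionResult:
    """Outcome of a panel-selection run.

    Attributes
    ----------
    method : {'logistic', 'rf', 'random', 'none'}
    per_class_genes : dict or None
        For the logistic selector: class -> list of (gene, |coefficient|)
        pairs sorted by non-increasing score.
    ranked_genes : list or None
        For rf/random: one global (gene, score) ranking.
    combined_panel : list of str
        Deduplicated union, original-encounter order (class order, then
        rank order within class).
    budget : int or str
        The requested per-class or total gene number ('all' for none).
    seed : int or None
    """

    method: str
    combined_panel: list[str]
    budget: int | str
    per_class_genes: dict[str, list[tuple[str, float]]] | None = None
    ranked_genes: list[tuple[str, float]] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(set(self.combined_panel)) != len(self.combined_panel):
            raise ValueError("combined_panel contains duplicates")


def _ranked_order(scores: np.ndarray, gene_ids: Sequence[str]) -> np.ndarray:
    """Indices sorted by descending score, ties broken by ascending gene id."""
    order = np.lexsort((np.asarray(gene_ids, dtype=object), -scores))
    return order


def union_panel(per_class: dict[str, list[tuple[str, float]]]) -> list[str]:
    """Deduplicated union of per-class lists, original-encounter order."""
    seen: dict[str, None] = {}
    for cls in per_class:
        for gene, _ in per_class[cls]:
            seen.setdefault(gene, None)
    return list(seen)


class LogisticPanelSelector(TransformerMixin, BaseEstimator):
    """Per-class gene selection by multinomial-regression coefficient size.

    Fits one multinomial logistic model with an L2 penalty on ALL genes
    (one joint fit, not per-class one-vs-rest fits), then for each class
    ranks genes by the absolute value of that class's coefficient row and
    keeps the top ``n_per_class``. The fitted panel is the deduplicated
    union across classes.

    Parameters
    ----------
    n_per_class : int
        Genes to keep per class (clamped to the gene count, with a warning).
    l2_strength : float, default 1e-4
        Regularization strength; the model is fit with C = 1/l2_strength
        (10,000 by default, i.e. nearly unpenalized).
    max_iter : int, default 5000
        Iteration cap for the convex solver; hitting it raises.
    tol : float, default 1e-6
        Gradient tolerance.
    """

    def __init__(
        self,
        n_per_class: int = 80,
        l2_strength: float = DEFAULT_L2_STRENGTH,
        max_iter: int = 5000,
        tol: float = 1e-6,
    ):
        self.n_per_class = n_per_class
        self.l2_strength = l2_strength
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        X = pd.DataFrame(X)
        gene_ids = [str(g) for g in X.columns]
        classes = np.unique(np.asarray(y))
        if classes.size < 2:
            raise ValueError("panel selection needs at least 2 classes")
        n_keep = self.n_per_class
        if n_keep > len(gene_ids):
            warnings.warn(
                f"n_per_class={n_keep} exceeds gene count {len(gene_ids)}; clamping"
            )
            n_keep = len(gene_ids)
        # L2 penalty (the estimator's default) with C = 1/strength
        model = LogisticRegression(
            C=1.0 / self.l2_strength,
            solver="lbfgs",
            max_iter=self.max_iter,
            tol=self.tol,
        )
        model.fit(X.to_numpy(dtype=float), y)
        if np.any(np.asarray(model.n_iter_) >= self.max_iter):
            raise RuntimeError(
                "multinomial logistic selection did not converge within "
                f"{self.max_iter} iterations; standardized input "
                "(log2 + within-sample z-score) usually fixes this"
            )
        coef = model.coef_
        if coef.shape[0] == 1:
            # binary fit: one signed row serves both classes symmetrically
            coef = np.vstack([-coef[0], coef[0]])
        per_class: dict[str, list[tuple[str, float]]] = {}
        for ci, cls in enumerate(model.classes_):
            scores = np.abs(coef[ci])
            order = _ranked_order(scores, gene_ids)[:n_keep]
            per_class[str(cls)] = [(gene_ids[j], float(scores[j])) for j in order]
        self.classes_ = model.classes_
        self.result_ = SelectionResult(
            method="logistic",
            combined_panel=union_panel(per_class),
            budget=n_keep,
            per_class_genes=per_class,
        )
        self.panel_ = self.result_.combined_panel
        return self

    def transform(self, X):
        X = pd.DataFrame(X)
        return X[self.panel_]


class RandomForestPanelSelector(TransformerMixin, BaseEstimator):
    """Global gene ranking by Gini-impurity feature importance.

    A forest of ``n_trees`` bootstrap trees (per-tree feature cap = sqrt
    of the gene count, Gini splitting) is fit on all genes; genes are
    ranked by impurity importance and the top ``n_total`` form the panel.
    """

    def __init__(
        self,
        n_total: int = 800,
        n_trees: int = DEFAULT_SELECTOR_TREES,
        random_state: int | None = None,
    ):
        self.n_total = n_total
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        X = pd.DataFrame(X)
        gene_ids = [str(g) for g in X.columns]
        n_keep = self.n_total
        if n_keep > len(gene_ids):
            warnings.warn(
                f"n_total={n_keep} exceeds gene count {len(gene_ids)}; clamping"
            )
            n_keep = len(gene_ids)
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_features="sqrt",
            bootstrap=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        forest.fit(X.to_numpy(dtype=float), np.asarray(y))
        scores = forest.feature_importances_
        order = _ranked_order(scores, gene_ids)
        ranking = [(gene_ids[j], float(scores[j])) for j in order]
        self.result_ = SelectionResult(
            method="rf",
            combined_panel=[g for g, _ in ranking[:n_keep]],
            budget=n_keep,
            ranked_genes=ranking,
            seed=self.random_state,
        )
        self.panel_ = self.result_.combined_panel
        return self

    def transform(self, X):
        return pd.DataFrame(X)[self.panel_]


class RandomPanelSelector(TransformerMixin, BaseEstimator):
    """Uniform random gene panel (the no-information baseline)."""

    def __init__(self, n_total: int = 800, random_state: int | None = None):
        self.n_total = n_total
        self.random_state = random_state

    def fit(self, X, y=None):
        X = pd.DataFrame(X)
        gene_ids = [str(g) for g in X.columns]
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1 (empty panel is meaningless)")
        if self.n_total > len(gene_ids):
            raise ValueError(
                f"n_total={self.n_total} exceeds gene count {len(gene_ids)}"
            )
        rng = np.random.default_rng(self.random_state)
        picked = rng.choice(len(gene_ids), size=self.n_total, replace=False)
        self.result_ = SelectionResult(
            method="random",
            combined_panel=[gene_ids[j] for j in picked],
            budget=self.n_total,
            ranked_genes=[(gene_ids[j], 1.0) for j in picked],
            seed=self.random_state,
        )
        self.panel_ = self.result_.combined_panel
        return self

    def transform(self, X):
        return pd.DataFrame(X)[self.panel_]


class AllGenesSelector(TransformerMixin, BaseEstimator):
    """Identity selection: the panel is every gene (no feature selection)."""

    def fit(self, X, y=None):
        gene_ids = [str(g) for g in pd.DataFrame(X).columns]
        self.result_ = SelectionResult(
            method="none", combined_panel=gene_ids, budget="all"
        )
        self.panel_ = gene_ids
        return self

    def transform(self, X):
        return pd.DataFrame(X)[self.panel_]


#: selection method registry
SELECTION_METHODS = ("logistic", "rf", "random", "none")


def resolve_gene_budget(nominal_total: int | None, method: str, n_classes: int | None = None):
    """Map a nominal total gene number to the selector's effective budget.

    For the logistic selector the grid convention divides the nominal
    total by 10 to get a per-class count (minimum 1); rf/random use the
    nominal number as a global count; 'none' uses all genes.
    """
    if method == "none":
        return "all"
    if nominal_total is None or nominal_total < 1:
        raise ValueError("nominal_total must be a positive integer")
    if method == "logistic":
        return max(1, nominal_total // LOGISTIC_BUDGET_DIVISOR)
    if method in ("rf", "random"):
        return int(nominal_total)
    raise ValueError(f"unknown selection method {method!r}")


def make_selector(
    method: str,
    budget: int | None = None,
    seed: int | None = None,
    n_trees: int = DEFAULT_SELECTOR_TREES,
    l2_strength: float = DEFAULT_L2_STRENGTH,
) -> BaseEstimator:
    """Instantiate a selector with its EFFECTIVE budget.

    ``budget`` is per-class for 'logistic', total for 'rf'/'random',
    ignored for 'none' (see :func:`resolve_gene_budget` for the
    nominal-to-effective mapping).
    """
    if method == "logistic":
        return LogisticPanelSelector(n_per_class=budget, l2_strength=l2_strength)
    if method == "rf":
        return RandomForestPanelSelector(
            n_total=budget, n_trees=n_trees, random_state=seed
        )
    if method == "random":
        return RandomPanelSelector(n_total=budget, random_state=seed)
    if method == "none":
        return AllGenesSelector()
    raise ValueError(f"unknown selection method {method!r}")


def select_by_logistic(
    X, y, n_per_class: int, l2_strength: float = DEFAULT_L2_STRENGTH
) -> SelectionResult:
    """Functional wrapper around :class:`LogisticPanelSelector`."""
    return LogisticPanelSelector(
        n_per_class=n_per_class, l2_strength=l2_strength
    ).fit(X, y).result_


def select_by_random_forest(
    X, y, n_total: int, n_trees: int = DEFAULT_SELECTOR_TREES, seed: int | None = None
) -> SelectionResult:
    """Functional wrapper around :class:`RandomForestPanelSelector`."""
    return RandomForestPanelSelector(
        n_total=n_total, n_trees=n_trees, random_state=seed
    ).fit(X, y).result_


def select_random(gene_ids: Sequence[str], n_total: int, seed: int | None = None) -> SelectionResult:
    """Uniform random panel from an explicit gene list."""
    X = pd.DataFrame(np.zeros((1, len(gene_ids))), columns=list(gene_ids))
    return RandomPanelSelector(n_total=n_total, random_state=seed).fit(X).result_
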