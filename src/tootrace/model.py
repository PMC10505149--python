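"""The tissue-of-origin classifier: a frozen preprocessing + panel recipe
around one of four classification algorithms.

``TissueOfOriginClassifier`` is a scikit-learn estimator. ``fit`` takes a
samples x genes DataFrame of raw (TPM-like) expression and class labels;
internally it applies the per-sample preprocessing to the FULL gene
vector, restricts to the gene panel, and fits the inner classifier.
Normalizing before subsetting keeps each sample's within-sample mean/sd
(and proportion denominator) independent of the panel size — the numbers
differ if you normalize after subsetting, so the order is part of the
model contract.

Because preprocessing is strictly per sample, prediction is per sample
too: scoring a batch equals scoring each specimen alone, which is what
makes single-sample clinical application and cross-cohort transfer
possible without any training-cohort statistics leaking into the test
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .preprocess import DEFAULT_PSEUDOCOUNT, apply_preprocessing

#: classifier kind registry
CLASSIFIER_KINDS = ("lr", "rf", "knn", "svm")

# "Default parameters" are pinned explicitly so behavior cannot drift
# with library versions.
# L2 penalty is the estimator's default and is left implicit
LR_DEFAULTS = dict(C=1.0, solver="lbfgs", max_iter=5000)
RF_DEFAULTS = dict(n_estimators=100, criterion="gini", max_features="sqrt")
KNN_DEFAULT_K = 5
SVM_DEFAULTS = dict(kernel="rbf", C=10_000.0)

_MANIFEST = "manifest.json"
_STATE = "state.joblib"


@dataclass
class PredictionReport:
    """Per-sample predictions with class probabilities.

    ``probabilities`` rows sum to 1; ``predicted`` is the argmax class
    (ties broken by class order). For the SVM the probabilities are a
    softmax over one-vs-all decision values, a monotone surrogate rather
    than calibrated probabilities.
    """

    sample_ids: list[str]
    predicted: list[str]
    probabilities: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        out = self.probabilities.copy()
        out.insert(0, "predicted_class", self.predicted)
        out.index.name = "sample_id"
        return out


class TissueOfOriginClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class tissue-of-origin classifier over a gene panel.

    Parameters
    ----------
    preprocess : {'l1', 'log2std', None}, default 'log2std'
        Per-sample normalization applied to the full gene vector before
        panel restriction.
    classifier : {'lr', 'rf', 'knn', 'svm'}, default 'lr'
        Inner algorithm: multinomial logistic regression (L2, C=1),
        random forest (100 Gini trees, sqrt feature cap), k-nearest
        neighbors (k=5), or one-vs-all RBF SVM with C=10,000.
    panel : sequence of gene ids or None
        Feature panel; None means all training genes.
    pseudocount : float, default 1e-6
        Pseudocount for the log2 transform.
    n_neighbors, n_trees, svm_C, lr_C : kind-specific settings.
    random_state : int or None
        Seed for the stochastic inner classifiers (rf).

    Attributes
    ----------
    classes_ : ndarray of ordered class names.
    genes_ : list of training gene ids (full preprocessing space).
    panel_ : list of panel gene ids actually used as features.
    estimator_ : the fitted inner scikit-learn classifier.
    """

    def __init__(
        self,
        preprocess: str | None = "log2std",
        classifier: str = "lr",
        panel=None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        n_neighbors: int = KNN_DEFAULT_K,
        n_trees: int = RF_DEFAULTS["n_estimators"],
        svm_C: float = SVM_DEFAULTS["C"],
        lr_C: float = LR_DEFAULTS["C"],
        random_state: int | None = None,
    ):
        self.preprocess = preprocess
        self.classifier = classifier
        self.panel = panel
        self.pseudocount = pseudocount
        self.n_neighbors = n_neighbors
        self.n_trees = n_trees
        self.svm_C = svm_C
        self.lr_C = lr_C
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _make_estimator(self):
        if self.classifier == "lr":
            params = dict(LR_DEFAULTS, C=self.lr_C)
            return LogisticRegression(**params)
        if self.classifier == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_trees,
                criterion=RF_DEFAULTS["criterion"],
                max_features=RF_DEFAULTS["max_features"],
                random_state=self.random_state,
                n_jobs=1,
            )
        if self.classifier == "knn":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors)
        if self.classifier == "svm":
            return OneVsRestClassifier(
                SVC(kernel=SVM_DEFAULTS["kernel"], C=self.svm_C)
            )
        raise ValueError(f"unknown classifier kind {self.classifier!r}")

    def _prepare(self, X: pd.DataFrame, fitting: bool) -> np.ndarray:
        """Preprocess the full gene vector, then restrict to the panel."""
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(X)
            if not fitting:
                X.columns = self.genes_[: X.shape[1]]
        if fitting:
            genes = [str(g) for g in X.columns]
        else:
            genes = self.genes_
            missing_panel = [g for g in self.panel_ if g not in X.columns]
            if missing_panel:
                raise ValueError(f"matrix is missing panel genes: {missing_panel[:10]}")
            if self.preprocess is not None:
                missing = [g for g in genes if g not in X.columns]
                if missing:
                    raise ValueError(
                        f"matrix is missing {len(missing)} non-panel training genes "
                        f"(e.g. {missing[:5]}); per-sample preprocessing "
                        f"({self.preprocess!r}) computes within-sample statistics "
                        "over the FULL training gene vector, so every training "
                        "gene must be present"
                    )
                X = X[genes]
            else:
                X = X[self.panel_]
                genes = self.panel_
        prepped = apply_preprocessing(
            X, self.preprocess, pseudocount=self.pseudocount
        )
        prepped = pd.DataFrame(np.asarray(prepped), index=X.index, columns=genes)
        panel = self.panel_ if not fitting else self._resolved_panel(genes)
        return prepped[panel].to_numpy(dtype=float)

    def _resolved_panel(self, genes: list[str]) -> list[str]:
        if self.panel is None:
            return list(genes)
        panel = [str(g) for g in self.panel]
        if len(set(panel)) != len(panel):
            raise ValueError("panel contains duplicate gene ids")
        missing = [g for g in panel if g not in set(genes)]
        if missing:
            raise ValueError(f"panel genes absent from dataset: {missing[:10]}")
        return panel

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("label count does not match sample count")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("training needs at least 2 classes")
        self.genes_ = [str(g) for g in X.columns]
        self.panel_ = self._resolved_panel(self.genes_)
        features = self._prepare(X, fitting=True)
        self.estimator_ = self._make_estimator()
        self.estimator_.fit(features, y)
        self.training_fingerprint_ = {
            "n_samples": int(X.shape[0]),
            "n_genes": int(X.shape[1]),
            "n_classes": int(self.classes_.size),
            "random_state": self.random_state,
        }
        return self

    def _scores(self, X) -> np.ndarray:
        """Class scores with rows summing to 1, columns in classes_ order."""
        features = self._prepare(pd.DataFrame(X), fitting=False)
        est = self.estimator_
        if self.classifier == "svm":
            decision = est.decision_function(features)
            if decision.ndim == 1:  # binary one-vs-rest
                decision = np.column_stack([-decision, decision])
            proba = softmax(decision, axis=1)
            order = est.classes_
        else:
            proba = est.predict_proba(features)
            order = est.classes_
        # reorder columns into self.classes_ order
        col = {c: i for i, c in enumerate(order)}
        proba = proba[:, [col[c] for c in self.classes_]]
        return proba / proba.sum(axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        return self._scores(X)

    def predict(self, X) -> np.ndarray:
        proba = self._scores(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def predict_report(self, X) -> PredictionReport:
        X = pd.DataFrame(X)
        proba = self._scores(X)
        predicted = self.classes_[np.argmax(proba, axis=1)]
        frame = pd.DataFrame(
            proba, index=X.index, columns=[str(c) for c in self.classes_]
        )
        return PredictionReport(
            sample_ids=[str(s) for s in X.index],
            predicted=[str(p) for p in predicted],
            probabilities=frame,
        )

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize to a directory: human-diffable manifest + fitted state."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "format": "tootrace-model/1",
            "params": {
                "preprocess": self.preprocess,
                "classifier": self.classifier,
                "pseudocount": self.pseudocount,
                "n_neighbors": self.n_neighbors,
                "n_trees": self.n_trees,
                "svm_C": self.svm_C,
                "lr_C": self.lr_C,
                "random_state": self.random_state,
            },
            "classes": [str(c) for c in self.classes_],
            "panel": list(self.panel_),
            "genes": list(self.genes_),
            "training_fingerprint": self.training_fingerprint_,
        }
        (path / _MANIFEST).write_text(json.dumps(manifest, indent=1))
        joblib.dump(self.estimator_, path / _STATE)

    @classmethod
    def load(cls, path: str | Path) -> "TissueOfOriginClassifier":
        path = Path(path)
        manifest = json.loads((path / _MANIFEST).read_text())
        if manifest.get("format") != "tootrace-model/1":
            raise ValueError(f"{path} is not a serialized model directory")
        model = cls(panel=manifest["panel"], **manifest["params"])
        model.classes_ = np.asarray(manifest["classes"])
        model.panel_ = list(manifest["panel"])
        model.genes_ = list(manifest["genes"])
        model.training_fingerprint_ = manifest["training_fingerprint"]
        model.estimator_ = joblib.load(path / _STATE)
        return model


def train_model(
    X,
    y,
    preprocess: str | None = "log2std",
    panel=None,
    classifier: str = "lr",
    seed: int | None = None,
    **params,
) -> TissueOfOriginClassifier:
    """Fit a :class:`TissueOfOriginClassifier` with an explicit recipe."""
    model = TissueOfOriginClassifier(
        preprocess=preprocess,
        classifier=classifier,
        panel=panel,
        random_state=seed,
        **params,
    )
    return model.fit(X, y)


def predict(model: TissueOfOriginClassifier, X) -> PredictionReport:
    """Score an expression matrix with a trained model."""
    return model.predict_report(X)
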