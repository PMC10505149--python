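"""Cross-cohort application: gene-space harmonization, re-selection,
retraining, and external scoring.

Two RNA-seq cohorts rarely quantify the same gene set (different
annotation releases, platforms, expression-calling pipelines). The
transfer protocol is: restrict BOTH cohorts to the gene-id intersection,
re-run feature selection and model training on the restricted training
cohort, then score the external cohort per sample. Re-selection happens
AFTER intersection, so the final panel is always a subset of the shared
gene space. Gene ids are treated as opaque strings — symbol/Ensembl
mapping is the caller's responsibility.

Expression-unit mismatch between cohorts is deliberately not corrected
beyond the per-sample normalization; this is a documented limitation,
not an oversight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .model import PredictionReport, TissueOfOriginClassifier
from .preprocess import apply_preprocessing
from .select import make_selector

logger = logging.getLogger(__name__)


@dataclass
class HarmonizedPair:
    """Train and test cohorts restricted to their shared gene space."""

    train_X: pd.DataFrame
    train_y: pd.Series
    test_X: pd.DataFrame
    shared_genes: list[str]
    dropped_train: int
    dropped_test: int


def harmonize_genes(train_X: pd.DataFrame, train_y, test_X: pd.DataFrame) -> HarmonizedPair:
    """Restrict both matrices to the ordered gene-id intersection.

    The shared genes keep the training matrix's column order; drop
    counts for each side are logged and returned.
    """
    train_X = pd.DataFrame(train_X)
    test_X = pd.DataFrame(test_X)
    if train_X.shape[0] == 0 or test_X.shape[0] == 0:
        raise ValueError("both cohorts must be non-empty")
    test_genes = set(map(str, test_X.columns))
    shared = [g for g in map(str, train_X.columns) if g in test_genes]
    if not shared:
        raise ValueError("no genes shared between the two cohorts")
    dropped_train = train_X.shape[1] - len(shared)
    dropped_test = test_X.shape[1] - len(shared)
    logger.info(
        "harmonized to %d shared genes (dropped %d train, %d test)",
        len(shared), dropped_train, dropped_test,
    )
    y = pd.Series(train_y)
    y.index = train_X.index
    return HarmonizedPair(
        train_X=train_X[shared],
        train_y=y,
        test_X=test_X[shared],
        shared_genes=shared,
        dropped_train=dropped_train,
        dropped_test=dropped_test,
    )


def cross_cohort_fit(
    train_X: pd.DataFrame,
    train_y,
    test_X: pd.DataFrame,
    preprocess: str | None = "log2std",
    selector: str = "logistic",
    budget: int = 80,
    classifier: str = "lr",
    seed: int | None = 0,
    selector_params: dict | None = None,
    classifier_params: dict | None = None,
) -> tuple[TissueOfOriginClassifier, PredictionReport, HarmonizedPair]:
    """Harmonize, re-select, retrain, and score the external cohort.

    ``budget`` is the selector's effective budget on the restricted gene
    space: per-class for 'logistic', total for 'rf'/'random'. Test
    samples are preprocessed per sample, so predictions are invariant to
    which other external samples accompany them.
    """
    pair = harmonize_genes(train_X, train_y, test_X)
    if selector == "none":
        panel = None
    else:
        sel = make_selector(
            selector, budget=budget, seed=seed, **(selector_params or {})
        )
        prepped = apply_preprocessing(pair.train_X, preprocess)
        sel.fit(
            pd.DataFrame(
                prepped, index=pair.train_X.index, columns=pair.train_X.columns
            ),
            pair.train_y,
        )
        panel = sel.panel_
    model = TissueOfOriginClassifier(
        preprocess=preprocess,
        classifier=classifier,
        panel=panel,
        random_state=seed,
        **(classifier_params or {}),
    ).fit(pair.train_X, pair.train_y)
    report = model.predict_report(pair.test_X)
    return model, report, pair
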