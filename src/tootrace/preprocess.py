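"""Per-sample expression normalizations.

Two normalizations are compared throughout the package, both strictly
per sample so that a single new specimen can be scored without any
cohort statistics:

* **L1 proportion scaling** — each sample's expression vector is divided
  by its own sum, ``G = g / sum(g)``, turning TPM-like values into
  proportions that sum to 1.
* **log2 + within-sample standardization** — each value is shifted by a
  small pseudocount (default 1e-6, to avoid log2(0)), log2-transformed,
  then z-scored using that sample's own mean and standard deviation:
  ``z = (x - u) / s``.

Both are exposed as stateless scikit-learn transformers (``fit`` only
validates) and as plain functions. Standardization is WITHIN-sample
(across genes), not per-gene across the cohort — the less common
convention, chosen deliberately: it is what makes application to a lone
clinical sample, or to an external cohort, leakage-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

#: pseudocount added before log2 during preprocessing
DEFAULT_PSEUDOCOUNT = 1e-6
#: delta degrees of freedom for the within-sample sd (0 = population sd)
SD_DDOF = 0


def _as_frame(X) -> tuple[np.ndarray, pd.DataFrame | None]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), X
    return np.asarray(X, dtype=float), None


def _rewrap(values: np.ndarray, frame: pd.DataFrame | None):
    if frame is None:
        return values
    return pd.DataFrame(values, index=frame.index, columns=frame.columns)


def _sample_name(frame: pd.DataFrame | None, i: int) -> str:
    return repr(frame.index[i]) if frame is not None else f"#{i}"


def l1_normalize(X):
    """Scale each sample (row) to unit sum.

    Raises ``ValueError`` naming the sample if a row is all zero, and on
    negative input (proportions of a signed vector are meaningless).
    """
    values, frame = _as_frame(X)
    if (values < 0).any():
        raise ValueError("l1 normalization requires non-negative expression")
    totals = values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero total expression in sample {_sample_name(frame, zero[0])}"
        )
    return _rewrap(values / totals[:, None], frame)


def log2_standardize(X, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """log2(value + pseudocount), then z-score within each sample.

    Every output row has mean 0 and population sd 1. Raises
    ``ValueError`` naming the sample if a row has zero variance after
    the log transform (z-scores would be undefined).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    values, frame = _as_frame(X)
    if (values < 0).any():
        raise ValueError("log2 standardization requires non-negative expression")
    with np.errstate(divide="raise"):
        logged = np.log2(values + pseudocount)
    u = logged.mean(axis=1)
    s = logged.std(axis=1, ddof=SD_DDOF)
    # a constant row can leave a tiny rounding residue in s, so detect
    # zero variance from the value range, not from s == 0
    zero = np.flatnonzero(
        (s == 0) | (np.ptp(logged, axis=1) == 0)
    )
    if zero.size:
        raise ValueError(
            f"zero within-sample variance in sample {_sample_name(frame, zero[0])}"
        )
    return _rewrap((logged - u[:, None]) / s[:, None], frame)


class L1Normalizer(TransformerMixin, BaseEstimator):
    """Stateless per-sample L1 (proportion) normalizer.

    ``fit`` learns nothing — each sample is scaled by its own total — so
    transforming a batch equals transforming each sample alone.
    """

    def fit(self, X, y=None):
        values, _ = _as_frame(X)
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X):
        return l1_normalize(X)


class Log2Standardizer(TransformerMixin, BaseEstimator):
    """Stateless per-sample log2 + z-score transformer.

    Parameters
    ----------
    pseudocount : float, default 1e-6
        Added to every value before log2 to avoid log2(0).
    """

    def __init__(self, pseudocount: float = DEFAULT_PSEUDOCOUNT):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        values, _ = _as_frame(X)
        self.n_features_in_ = values.shape[1]
        return self

    def transform(self, X):
        return log2_standardize(X, pseudocount=self.pseudocount)


#: preprocessing method registry used by models, CV and the CLI
PREPROCESS_METHODS = ("l1", "log2std")


def get_preprocessor(
    method: str | None, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> TransformerMixin | None:
    """Transformer for a named preprocessing method (None = raw values)."""
    if method is None or method == "none":
        return None
    if method == "l1":
        return L1Normalizer()
    if method == "log2std":
        return Log2Standardizer(pseudocount=pseudocount)
    raise ValueError(f"unknown preprocessing method {method!r}")


def apply_preprocessing(X, method: str | None, pseudocount: float = DEFAULT_PSEUDOCOUNT):
    """Apply a named preprocessing method (or pass through for None)."""
    prep = get_preprocessor(method, pseudocount=pseudocount)
    if prep is None:
        values, frame = _as_frame(X)
        return _rewrap(values, frame)
    return prep.fit_transform(X)
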