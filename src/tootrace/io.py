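"""Reading and writing expression matrices, labels, gene lists and label maps.

The in-memory carrier for an expression matrix is a pandas DataFrame in
canonical orientation: rows = samples, columns = genes, values = TPM-like
non-negative expression. The canonical on-disk layout is gene-major
(first column = gene id, remaining columns = samples), matching how both
GDC and ICGC export bulk expression tables; an orientation flag handles
the transpose.

Labels travel in a separate two-column file (sample_id, label) joined by
sample id. TCGA-style barcodes are parsed for the sample-type code in the
4th field so cohorts can be split into primary and metastatic subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: barcode sample-type codes counted as primary tumors
PRIMARY_CODES = frozenset({"01", "03"})
#: barcode sample-type codes counted as metastatic tumors
METASTATIC_CODES = frozenset({"06"})


class ExpressionTableError(ValueError):
    """Malformed expression table (duplicates, negatives, empties...)."""


@dataclass(frozen=True)
class SampleTypeCode:
    """Classification of a TCGA-style barcode's sample-type field."""

    category: str  # 'primary' | 'metastatic' | 'excluded'
    raw_code: str


@dataclass
class LabeledDataset:
    """An expression matrix plus one class label per sample."""

    X: pd.DataFrame
    y: pd.Series

    def __post_init__(self) -> None:
        if len(self.y) != self.X.shape[0]:
            raise ValueError(
                f"label count ({len(self.y)}) != sample count ({self.X.shape[0]})"
            )
        if not self.y.index.equals(self.X.index):
            self.y = self.y.reindex(self.X.index)
            if self.y.isna().any():
                missing = list(self.y[self.y.isna()].index[:5])
                raise ValueError(f"samples without a label: {missing}")

    @property
    def class_names(self) -> list[str]:
        return sorted(self.y.unique())

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]


def validate_expression(X: pd.DataFrame, allow_negative: bool = False) -> None:
    """Enforce the expression-matrix invariants, raising with coordinates."""
    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ExpressionTableError("empty expression table")
    dup_samples = X.index[X.index.duplicated()].unique().tolist()
    if dup_samples:
        raise ExpressionTableError(f"duplicate sample ids: {dup_samples}")
    dup_genes = X.columns[X.columns.duplicated()].unique().tolist()
    if dup_genes:
        raise ExpressionTableError(f"duplicate gene ids: {dup_genes}")
    values = X.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.zeros(X.shape, dtype=bool)
        for j in range(X.shape[1]):
            col = pd.to_numeric(X.iloc[:, j], errors="coerce")
            bad[:, j] = col.isna().to_numpy() & X.iloc[:, j].notna().to_numpy()
        i, j = np.argwhere(bad)[0] if bad.any() else (0, 0)
        raise ExpressionTableError(
            f"non-numeric value at sample {X.index[i]!r}, gene {X.columns[j]!r}"
        )
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ExpressionTableError(
            f"non-finite value at sample {X.index[i]!r}, gene {X.columns[j]!r}"
        )
    if not allow_negative and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ExpressionTableError(
            f"negative value {values[i, j]} at sample {X.index[i]!r}, "
            f"gene {X.columns[j]!r}"
        )


def read_expression_table(
    path: str | Path,
    genes_in: str = "rows",
    delimiter: str = "\t",
    allow_negative: bool = False,
) -> pd.DataFrame:
    """Read a delimited expression table into samples x genes orientation.

    Parameters
    ----------
    path : file path
        Delimited text with a header line and an id column.
    genes_in : {'rows', 'columns'}
        On-disk layout. ``'rows'`` (default) means the first column holds
        gene ids and each remaining column is a sample.
    delimiter : str
        Field separator.
    allow_negative : bool
        Permit negative values (already-transformed matrices); raw
        expression must be non-negative.
    """
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")
    table = pd.read_csv(path, sep=delimiter, index_col=0)
    if genes_in == "rows":
        table = table.T
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    table.index.name = "sample_id"
    table.columns.name = "gene_id"
    validate_expression(table, allow_negative=allow_negative)
    return table.astype(float)


def write_expression_table(
    X: pd.DataFrame,
    path: str | Path,
    genes_in: str = "rows",
    delimiter: str = "\t",
) -> None:
    """Write a samples x genes DataFrame as delimited text (full precision)."""
    if genes_in not in ("rows", "columns"):
        raise ValueError("genes_in must be 'rows' or 'columns'")
    out = X.T if genes_in == "rows" else X
    out = out.rename_axis("gene_id" if genes_in == "rows" else "sample_id")
    out.to_csv(path, sep=delimiter)


def read_labels(path: str | Path, delimiter: str = "\t") -> pd.Series:
    """Read a two-column (sample_id, label) file into a Series."""
    table = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if table.shape[1] < 1:
        raise ValueError(f"label file {path} needs two columns (sample_id, label)")
    labels = table.iloc[:, 0]
    labels.index = labels.index.astype(str)
    labels.name = "label"
    return labels


def write_labels(y: pd.Series, path: str | Path, delimiter: str = "\t") -> None:
    y.rename("label").rename_axis("sample_id").to_csv(path, sep=delimiter)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene id per line; blank lines ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_label_map(path: str | Path, delimiter: str = "\t") -> dict[str, str]:
    """Two-column (old_label, new_label) file, no header required."""
    table = pd.read_csv(path, sep=delimiter, header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"label map {path} needs two columns (old, new)")
    return dict(zip(table.iloc[:, 0], table.iloc[:, 1]))


def align_labels(X: pd.DataFrame, labels: pd.Series) -> LabeledDataset:
    """Join a label Series onto an expression matrix by sample id.

    Samples without a label are dropped (with a logged count); labels for
    unknown samples are ignored.
    """
    keep = X.index.intersection(labels.index)
    dropped = X.shape[0] - len(keep)
    if dropped:
        logger.info("dropping %d samples without a label", dropped)
    if len(keep) == 0:
        raise ValueError("no sample ids shared between matrix and labels")
    X = X.loc[keep]
    return LabeledDataset(X=X, y=labels.loc[keep].copy())


def parse_tcga_sample_type(barcode: str) -> SampleTypeCode:
    """Classify a TCGA-style barcode by the two-digit code of its 4th field.

    Codes 01 and 03 are primary tumors, 06 is metastatic; every other
    code (e.g. 11, solid tissue normal) is excluded.
    """
    fields = str(barcode).split("-")
    if len(fields) < 4:
        raise ValueError(f"malformed barcode {barcode!r}: fewer than 4 fields")
    code = fields[3][:2]
    if len(code) < 2 or not code.isdigit():
        raise ValueError(
            f"malformed barcode {barcode!r}: 4th field must start with two digits"
        )
    if code in PRIMARY_CODES:
        category = "primary"
    elif code in METASTATIC_CODES:
        category = "metastatic"
    else:
        category = "excluded"
    return SampleTypeCode(category=category, raw_code=code)


def split_primary_metastatic(
    sample_ids: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Partition barcodes into (primary, metastatic); other codes dropped."""
    primary, metastatic = [], []
    n_excluded = 0
    for sid in sample_ids:
        cat = parse_tcga_sample_type(sid).category
        if cat == "primary":
            primary.append(sid)
        elif cat == "metastatic":
            metastatic.append(sid)
        else:
            n_excluded += 1
    if n_excluded:
        logger.info("excluded %d samples with out-of-scope type codes", n_excluded)
    return primary, metastatic


def merge_labels(dataset: LabeledDataset, label_map: Mapping[str, str]) -> LabeledDataset:
    """Replace each label by its image under ``label_map``.

    Labels absent from the map pass through unchanged. Sample order and
    the value matrix are untouched; only the class structure changes
    (e.g. merging COAD and READ into COADREAD).
    """
    y = dataset.y.map(lambda lab: label_map.get(lab, lab))
    return LabeledDataset(X=dataset.X, y=y)
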