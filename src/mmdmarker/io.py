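"""Expression-matrix and label-table I/O.

The package operates on a genes-by-samples matrix of non-negative,
FPKM-scale continuous expression values plus a table assigning every
sample to a tissue group (by default one of ``normal``, ``nat``,
``tumor``).  Matrices are exchanged as delimited text: first column gene
identifiers, header row sample identifiers.  Labels are a two-column
table ``sample_id<TAB>group``.

Values are used raw by default; ``log_transform`` offers an optional
log2(v + offset) transform for users who prefer compressed dynamic
range.  Missing values are rejected rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GroupLabels",
    "read_expression_table",
    "write_expression_table",
    "read_labels",
    "write_labels",
    "log_transform",
    "validate_pair",
    "DEFAULT_GROUPS",
]

#: canonical tissue-group tags, in the conventional display order
DEFAULT_GROUPS = ("normal", "nat", "tumor")


class ValidationError(ValueError):
    """Raised when a matrix or label table violates its invariants."""


def _find_duplicates(ids) -> list:
    seen, dups = set(), []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    return dups


@dataclass(frozen=True)
class ExpressionMatrix:
    """A genes × samples grid of finite, non-negative expression values.

    Parameters
    ----------
    gene_ids, sample_ids
        Ordered, duplicate-free identifier tuples.
    values
        Array of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: tuple
    sample_ids: tuple
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            dups = _find_duplicates(ids)
            if dups:
                raise ValidationError(f"duplicate {name} identifiers: {dups}")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value grid shape {vals.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(vals)):
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if np.any(vals < 0):
            g, s = np.argwhere(vals < 0)[0]
            raise ValidationError(
                f"negative expression value {vals[g, s]} at gene "
                f"{self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_values(self, gene_id) -> np.ndarray:
        """Expression vector of one gene across all samples."""
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None
        return self.values[i]

    def restrict_genes(self, gene_ids) -> "ExpressionMatrix":
        """Sub-matrix containing only ``gene_ids``, in the given order."""
        idx = [self.gene_ids.index(g) for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy(float))


@dataclass(frozen=True)
class GroupLabels:
    """Assignment of each sample identifier to a group tag.

    The tag set is open: any string is a legal group.  Comparisons and
    the estimators downstream additionally require at least two samples
    per referenced group.
    """

    assignment: Mapping[str, str]

    def __post_init__(self):
        object.__setattr__(self, "assignment", dict(self.assignment))

    def group_of(self, sample_id: str) -> str:
        return self.assignment[sample_id]

    def samples_in(self, group: str) -> tuple:
        return tuple(s for s, g in self.assignment.items() if g == group)

    def groups(self) -> tuple:
        seen = dict.fromkeys(self.assignment.values())
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.assignment)


def read_expression_table(
    path, delimiter: str = "\t", genes_as_rows: bool = True
) -> ExpressionMatrix:
    """Read a delimited expression table into an :class:`ExpressionMatrix`.

    The file's first column holds row identifiers and its header row the
    column identifiers.  With ``genes_as_rows=False`` the file is
    transposed after reading, so both orientations yield the canonical
    genes-as-rows matrix.
    """
    frame = pd.read_csv(path, sep=delimiter, index_col=0)
    if not genes_as_rows:
        frame = frame.T
    non_numeric = frame.columns[
        [not np.issubdtype(d, np.number) for d in frame.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad_row = frame.index[coerced.isna() & frame[col].notna()]
        where = f"row {bad_row[0]!r}, column {col!r}" if len(bad_row) else f"column {col!r}"
        raise ValidationError(f"non-numeric expression cell at {where} in {path}")
    if frame.isna().any().any():
        r, c = next(zip(*np.where(frame.isna().to_numpy())))
        raise ValidationError(
            f"missing expression value at row {frame.index[r]!r}, "
            f"column {frame.columns[c]!r} in {path}"
        )
    return ExpressionMatrix.from_frame(frame)


def write_expression_table(
    matrix: ExpressionMatrix, path, delimiter: str = "\t"
) -> None:
    """Write a matrix as delimited text (round-trips with the reader)."""
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep=delimiter, float_format="%.17g")


def read_labels(path, delimiter: str = "\t") -> GroupLabels:
    """Read a two-column ``sample_id, group`` table.

    Exact duplicate rows are deduplicated; the same sample listed with
    two different groups is a conflict and raises.
    """
    frame = pd.read_csv(path, sep=delimiter, dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError(f"label table {path} needs two columns, got {frame.shape[1]}")
    sample_col, group_col = frame.columns[:2]
    assignment: dict[str, str] = {}
    for sample, group in zip(frame[sample_col], frame[group_col]):
        if sample in assignment and assignment[sample] != group:
            raise ValidationError(
                f"sample {sample!r} listed with conflicting groups "
                f"{assignment[sample]!r} and {group!r}"
            )
        assignment[sample] = group
    return GroupLabels(assignment)


def write_labels(labels: GroupLabels, path, delimiter: str = "\t") -> None:
    frame = pd.DataFrame(
        {"sample_id": list(labels.assignment), "group": list(labels.assignment.values())}
    )
    frame.to_csv(path, sep=delimiter, index=False)


def log_transform(matrix: ExpressionMatrix, offset: float = 1.0) -> ExpressionMatrix:
    """Return a copy with every value v replaced by log2(v + offset).

    Monotone per gene, so downstream rankings of samples within a gene
    are unchanged; scores that depend on distances (MMD, t, fold change)
    of course are not.
    """
    if offset <= 0:
        raise ValueError(f"offset must be > 0, got {offset}")
    return ExpressionMatrix(
        matrix.gene_ids, matrix.sample_ids, np.log2(matrix.values + offset)
    )


def validate_pair(matrix: ExpressionMatrix, labels: GroupLabels) -> None:
    """Check that matrix samples and labelled samples coincide exactly."""
    m, l = set(matrix.sample_ids), set(labels.assignment)
    if m != l:
        raise ValidationError(
            "matrix and labels cover different samples; only in matrix: "
            f"{sorted(m - l)}, only in labels: {sorted(l - m)}"
        )
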