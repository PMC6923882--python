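"""Entropy-based discovery of expression-level boundaries between classes.

A marker gene is only clinically usable with a concrete expression
threshold separating tissue classes.  When the classes leave a clean
gap in expression, the threshold is just the edge of the gap; when they
overlap, this module picks the cut the way decision-tree induction
does: the class entropy of a labelled sample set D is

    Ent(D) = -Σ_k p_k log2 p_k      (0·log 0 := 0)

and a split point x partitions D into {e ≤ x} and {e > x} with
information gain

    Gain(D, x) = Ent(D) - Σ_v |D^v|/|D| · Ent(D^v).

Expression is continuous, so candidate splits are the midpoints between
consecutive distinct sorted values; the boundary is the candidate with
the highest gain (smallest threshold on ties, for determinism).  On
perfectly separated classes this recovers the midpoint of the gap, so
the gap heuristic is a special case.

Three classes (normal / NAT / tumor) are handled as two adjacent binary
problems after ordering the groups by median expression: low-vs-middle
yields threshold t1 and middle-vs-high yields t2, giving per-class
intervals low: e ≤ t1, middle: t1 < e < t2, high: e ≥ t2.  If noise
makes t1 ≥ t2 the result is flagged non-monotone instead of silently
reordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GroupLabels

__all__ = [
    "LabeledValues",
    "BoundaryResult",
    "entropy",
    "candidate_splits",
    "information_gain",
    "find_boundary",
    "three_class_boundaries",
    "boundary_table",
]


@dataclass(frozen=True)
class LabeledValues:
    """Parallel vectors of expression values and class tags."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).ravel()
        labs = tuple(self.labels)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", labs)
        if vals.size != len(labs):
            raise ValueError(
                f"values ({vals.size}) and labels ({len(labs)}) differ in length"
            )
        if vals.size < 2:
            raise ValueError("need at least 2 labelled values")
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite")

    def class_counts(self) -> dict:
        counts: dict = {}
        for lab in self.labels:
            counts[lab] = counts.get(lab, 0) + 1
        return counts


@dataclass(frozen=True)
class BoundaryResult:
    """Per-gene class thresholds and the expression interval of each class.

    ``group_order`` lists the groups by ascending median expression;
    ``thresholds`` are the adjacent-pair split points (t1, t2) with
    their information gains; ``intervals`` maps each group to its
    (lower, upper) expression range, open at ±inf for the outer classes.
    ``monotone`` is False when t1 ≥ t2, i.e. the two binary splits
    crossed and the intervals are not a valid partition.
    """

    gene_id: str
    group_order: tuple
    thresholds: tuple
    gains: tuple
    intervals: dict
    monotone: bool


def entropy(class_counts) -> float:
    """Class entropy in bits of a set summarised by per-class counts."""
    counts = np.asarray(list(class_counts), dtype=float)
    if np.any(counts < 0):
        raise ValueError(f"negative class count in {list(class_counts)}")
    total = counts.sum()
    if total < 1:
        raise ValueError("total count must be >= 1")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def candidate_splits(values) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values.

    Duplicated values collapse, so no candidate ever coincides with a
    data point.  Fewer than two distinct values yields an empty array.
    """
    distinct = np.unique(np.asarray(values, dtype=float))
    if distinct.size < 2:
        return np.empty(0)
    return (distinct[:-1] + distinct[1:]) / 2.0


def information_gain(data: LabeledValues, split: float) -> float:
    """Information gain of partitioning ``data`` at ``split``.

    Left child is {value ≤ split}, right child {value > split}.  The
    result lies in [0, Ent(D)], reaching Ent(D) iff both children are
    pure.
    """
    vals = data.values
    if not (vals.min() < split < vals.max()):
        raise ValueError(
            f"split {split} outside the open data range "
            f"({vals.min()}, {vals.max()})"
        )
    labels = np.asarray(data.labels, dtype=object)
    classes = np.unique(labels)
    parent_counts = [(labels == c).sum() for c in classes]
    left = vals <= split
    left_counts = [(labels[left] == c).sum() for c in classes]
    right_counts = [(labels[~left] == c).sum() for c in classes]
    n = vals.size
    gain = entropy(parent_counts)
    for counts in (left_counts, right_counts):
        size = sum(counts)
        if size:
            gain -= (size / n) * entropy(counts)
    return float(gain)


def find_boundary(data: LabeledValues) -> tuple[float, float]:
    """Best split point and its gain, by exhaustive midpoint search.

    Evaluates the information gain at every candidate split and returns
    the argmax; ties resolve to the smallest threshold.  All values
    identical (no candidate splits) or a single class present is an
    error.
    """
    if len(set(data.labels)) < 2:
        raise ValueError("need at least two classes to place a boundary")
    splits = candidate_splits(data.values)
    if splits.size == 0:
        raise ValueError("all expression values identical; no valid split exists")
    best_split, best_gain = None, -np.inf
    for split in splits:  # ascending, so ties keep the smallest threshold
        gain = information_gain(data, split)
        if gain > best_gain:
            best_split, best_gain = float(split), gain
    return best_split, float(best_gain)


def three_class_boundaries(
    matrix: ExpressionMatrix, labels: GroupLabels, gene, groups=None
) -> BoundaryResult:
    """Two expression thresholds separating three tissue groups.

    Groups are ordered by ascending median expression of the gene (the
    data, not a fixed tissue order, decides which class sits lowest —
    markers exist in both orientations).  Each adjacent pair of groups
    is then split by :func:`find_boundary`.
    """
    if groups is None:
        groups = labels.groups()
    groups = tuple(groups)
    if len(groups) != 3:
        raise ValueError(f"expected exactly 3 groups, got {groups}")
    values = matrix.gene_values(gene)
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    per_group = {}
    for g in groups:
        samples = labels.samples_in(g)
        if len(samples) < 2:
            raise ValueError(f"group {g!r} has {len(samples)} sample(s); need >= 2")
        per_group[g] = values[[col[s] for s in samples]]

    order = tuple(sorted(groups, key=lambda g: float(np.median(per_group[g]))))
    low, mid, high = order

    t1, g1 = find_boundary(
        LabeledValues(
            np.concatenate([per_group[low], per_group[mid]]),
            (low,) * per_group[low].size + (mid,) * per_group[mid].size,
        )
    )
    t2, g2 = find_boundary(
        LabeledValues(
            np.concatenate([per_group[mid], per_group[high]]),
            (mid,) * per_group[mid].size + (high,) * per_group[high].size,
        )
    )
    monotone = t1 < t2
    intervals = {
        low: (-np.inf, t1),
        mid: (t1, t2),
        high: (t2, np.inf),
    }
    return BoundaryResult(
        gene_id=gene,
        group_order=order,
        thresholds=(t1, t2),
        gains=(g1, g2),
        intervals=intervals,
        monotone=monotone,
    )


def boundary_table(
    matrix: ExpressionMatrix, labels: GroupLabels, genes, groups=None
) -> pd.DataFrame:
    """Per-class interval table for several genes (one row per gene×group).

    Columns: gene_id, group, interval_lower, interval_upper,
    threshold_gain, monotone_flag.  Outer intervals carry ±inf.
    """
    records = []
    for gene in genes:
        result = three_class_boundaries(matrix, labels, gene, groups=groups)
        gain_of = {
            result.group_order[0]: result.gains[0],
            result.group_order[1]: max(result.gains),
            result.group_order[2]: result.gains[1],
        }
        for group in result.group_order:
            lower, upper = result.intervals[group]
            records.append(
                (gene, group, lower, upper, gain_of[group], result.monotone)
            )
    return pd.DataFrame(
        records,
        columns=[
            "gene_id", "group", "interval_lower", "interval_upper",
            "threshold_gain", "monotone_flag",
        ],
    )
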