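"""Per-gene scoring, ranking and average-rank marker selection.

Every gene is scored on one or more pairwise group comparisons (e.g.
normal vs tumor) by one of three methods:

``mmd``
    unbiased Gaussian-kernel MMD² (higher = more different),
``ttest``
    two-sided two-sample t-test p-value (lower = more different),
``foldchange``
    |log2(E1/E2)| of the group mean expressions (higher = more
    different).

Within each comparison genes receive fractional ranks (rank 1 =
strongest signal; ties share the mean of the spanned positions, keeping
the rank sum at G(G+1)/2).  Markers are then selected by the smallest
average rank across a chosen subset of comparisons: the tumor-focused
preset averages the normal-vs-tumor and nat-vs-tumor ranks, the
all-pairs preset averages all three.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GroupLabels
from .mmd import KernelConfig, TwoSample, mmd2_unbiased

__all__ = [
    "ComparisonSpec",
    "DEFAULT_COMPARISONS",
    "TUMOR_FOCUSED_PRESET",
    "ALL_PAIRS_PRESET",
    "METHODS",
    "score_gene",
    "t_test_gene",
    "fold_change_gene",
    "rank_genes",
    "score_table",
    "average_rank",
    "top_k",
]

METHODS = ("mmd", "ttest", "foldchange")

#: score direction per method: True if a larger score means a stronger signal
_HIGHER_IS_STRONGER = {"mmd": True, "ttest": False, "foldchange": True}


@dataclass(frozen=True)
class ComparisonSpec:
    """A named pairwise contrast between two group tags."""

    name: str
    group_a: str
    group_b: str

    def __post_init__(self):
        if self.group_a == self.group_b:
            raise ValueError(f"comparison {self.name!r} contrasts a group with itself")


DEFAULT_COMPARISONS = (
    ComparisonSpec("normal_vs_nat", "normal", "nat"),
    ComparisonSpec("normal_vs_tumor", "normal", "tumor"),
    ComparisonSpec("nat_vs_tumor", "nat", "tumor"),
)

#: comparisons averaged for tumor-detection marker selection
TUMOR_FOCUSED_PRESET = ("normal_vs_tumor", "nat_vs_tumor")
#: comparisons averaged for the final three-group marker list
ALL_PAIRS_PRESET = ("normal_vs_nat", "normal_vs_tumor", "nat_vs_tumor")


def _group_vectors(matrix, labels, gene, comparison):
    values = matrix.gene_values(gene)
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    out = []
    for group in (comparison.group_a, comparison.group_b):
        samples = labels.samples_in(group)
        if len(samples) < 2:
            raise ValueError(
                f"group {group!r} has {len(samples)} sample(s); "
                f"gene {gene!r} needs at least 2 per group"
            )
        out.append(values[[col[s] for s in samples]])
    return out


def t_test_gene(x, y, welch: bool = False) -> float:
    """Two-sided two-sample t-test p-value (pooled variance by default).

    Degenerate inputs follow a fixed convention instead of propagating
    NaN: two constant groups give p = 1 when their values agree and
    p = 0 when they differ (certain difference with zero noise).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("t-test needs at least 2 values per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        return 1.0 if x[0] == y[0] else 0.0
    result = stats.ttest_ind(x, y, equal_var=not welch)
    return float(result.pvalue)


def fold_change_gene(x, y, pseudocount: float = 0.0) -> float:
    """|log2((mean(x)+c) / (mean(y)+c))| — symmetric under group swap.

    The default pseudocount c is 0; a zero group mean then raises with a
    pointer to the pseudocount rather than returning infinity (FPKM
    matrices often contain all-zero genes).
    """
    if pseudocount < 0:
        raise ValueError(f"pseudocount must be >= 0, got {pseudocount}")
    e1 = float(np.mean(x)) + pseudocount
    e2 = float(np.mean(y)) + pseudocount
    if e1 <= 0 or e2 <= 0:
        raise ValueError(
            "a group mean (plus pseudocount) is zero; fold change is undefined — "
            "pass a positive pseudocount (e.g. 1.0 on the FPKM scale)"
        )
    return abs(float(np.log2(e1 / e2)))


def score_gene(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    gene,
    comparison: ComparisonSpec,
    method: str = "mmd",
    config: KernelConfig = KernelConfig(),
    pseudocount: float = 0.0,
    welch: bool = False,
) -> float:
    """Score one gene on one comparison with the chosen method."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    x, y = _group_vectors(matrix, labels, gene, comparison)
    if method == "mmd":
        return mmd2_unbiased(TwoSample(x, y), config)
    if method == "ttest":
        return t_test_gene(x, y, welch=welch)
    return fold_change_gene(x, y, pseudocount=pseudocount)


def rank_genes(scores: pd.Series, direction: str = "higher_is_stronger") -> pd.Series:
    """Fractional ranks, rank 1 = strongest signal.

    ``direction`` says which end of the score scale is strong:
    ``higher_is_stronger`` for MMD and fold change,
    ``lower_is_stronger`` for p-values.
    """
    if direction not in ("higher_is_stronger", "lower_is_stronger"):
        raise ValueError(f"unknown direction {direction!r}")
    values = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(values)):
        bad = scores.index[~np.isfinite(values)][0]
        raise ValueError(f"non-finite score for gene {bad!r}")
    keyed = -values if direction == "higher_is_stronger" else values
    ranks = stats.rankdata(keyed, method="average")
    return pd.Series(ranks, index=scores.index, name="rank")


def score_table(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    comparisons=DEFAULT_COMPARISONS,
    methods=("mmd",),
    config: KernelConfig = KernelConfig(),
    pseudocount: float = 0.0,
    welch: bool = False,
) -> pd.DataFrame:
    """Score and rank every gene on every comparison × method.

    Returns a long-format table with columns ``gene_id``, ``comparison``,
    ``method``, ``score``, ``rank``; ranks are fractional within each
    (comparison, method) block.
    """
    records = []
    for comparison in comparisons:
        for method in methods:
            scores = pd.Series(
                {
                    gene: score_gene(
                        matrix, labels, gene, comparison, method,
                        config=config, pseudocount=pseudocount, welch=welch,
                    )
                    for gene in matrix.gene_ids
                }
            )
            ranks = rank_genes(scores, _direction_for(method))
            for gene in matrix.gene_ids:
                records.append(
                    (gene, comparison.name, method, scores[gene], ranks[gene])
                )
    return pd.DataFrame(
        records, columns=["gene_id", "comparison", "method", "score", "rank"]
    )


def _direction_for(method: str) -> str:
    return "higher_is_stronger" if _HIGHER_IS_STRONGER[method] else "lower_is_stronger"


def average_rank(table: pd.DataFrame, comparisons, method: str = "mmd") -> pd.Series:
    """Arithmetic mean of a gene's ranks over the named comparisons."""
    comparisons = tuple(comparisons)
    if not comparisons:
        raise ValueError("comparison subset must be non-empty")
    sub = table[(table["method"] == method) & table["comparison"].isin(comparisons)]
    present = set(sub["comparison"])
    missing = set(comparisons) - present
    if missing:
        raise ValueError(f"table has no ranks for comparisons {sorted(missing)}")
    wide = sub.pivot(index="gene_id", columns="comparison", values="rank")
    if wide.isna().any().any():
        raise ValueError("some genes lack ranks in the requested comparisons")
    return wide[list(comparisons)].mean(axis=1).rename("average_rank")


def top_k(average_ranks: pd.Series, k: int) -> list:
    """The k genes with the smallest average rank.

    Ties are broken by lexicographic gene id so the selection is
    deterministic.
    """
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > len(average_ranks):
        raise ValueError(f"k={k} exceeds the number of genes ({len(average_ranks)})")
    order = sorted(average_ranks.index, key=lambda g: (average_ranks[g], str(g)))
    return order[:k]
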