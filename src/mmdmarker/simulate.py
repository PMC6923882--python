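"""Synthetic three-group expression data with known ground truth.

The generator emulates the structure of a bulk FPKM cohort with three
tissue groups (normal, NAT, tumor): most genes are null — one shared
distribution in every group — while a configurable fraction are
differentially expressed with group-specific locations in a chosen
ordering (by default normal > NAT > tumor, the dominant orientation of
down-regulated tumor markers; the inverted pattern is available per
gene).  Alongside the matrix and labels it returns the construction
truth — which genes are DE, their true group locations and the true
midpoint thresholds between adjacent groups — so ranking power and
boundary recovery can be measured exactly.

Two baseline laws are offered.  ``lognormal`` (default) draws log
expression from a normal law, giving the right-skewed, strictly
positive values typical of FPKM; effect sizes are applied on the log
scale in units of the within-group log-sd, and the true thresholds are
the geometric midpoints between adjacent group medians.  ``normal``
draws raw values from a normal law truncated at zero, with effects and
thresholds on the raw scale — convenient when a test needs exact
arithmetic control of group separation.

One seed drives everything through per-gene substreams, so truncating
or extending the gene list never changes the values of the genes
already simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import DEFAULT_GROUPS, ExpressionMatrix, GroupLabels

__all__ = [
    "SimulationSpec",
    "SimulationTruth",
    "simulate_expression",
    "default_paper_shape",
]

#: per-group location multipliers for each ordering pattern: the groups
#: are placed at (multiplier · effect · within_sd) above the gene's base
_ORDERINGS = {
    "normal>nat>tumor": {"normal": 2, "nat": 1, "tumor": 0},
    "tumor>nat>normal": {"normal": 0, "nat": 1, "tumor": 2},
    "nat>tumor>normal": {"normal": 0, "nat": 2, "tumor": 1},
    "nat>normal>tumor": {"normal": 1, "nat": 2, "tumor": 0},
    "normal>tumor>nat": {"normal": 2, "nat": 0, "tumor": 1},
    "tumor>normal>nat": {"normal": 1, "nat": 0, "tumor": 2},
}


@dataclass(frozen=True)
class SimulationSpec:
    """Study design of a synthetic cohort.

    Parameters
    ----------
    n_genes
        Total genes; the first ``round(de_fraction · n_genes)`` are DE.
    group_sizes
        Samples per group, in the order (normal, nat, tumor); each ≥ 2.
    de_fraction
        Fraction of genes that are differentially expressed.
    effect_sizes
        Location shift between adjacent groups, in units of
        ``within_sd``; a scalar applies to every DE gene, a sequence is
        cycled over them.
    within_sd
        Within-group standard deviation (log scale for the lognormal
        law, raw scale otherwise).
    baseline_law
        ``"lognormal"`` or ``"normal"`` (truncated at 0).
    ordering_pattern
        Group ordering of the DE shifts, e.g. ``"normal>nat>tumor"``;
        scalar or sequence cycled over DE genes.
    base_location, base_spread
        Distribution of the per-gene baseline location (log-FPKM scale
        for lognormal): location ~ Normal(base_location, base_spread).
    seed
        Drives all randomness through per-gene substreams.
    """

    n_genes: int = 500
    group_sizes: tuple = (75, 12, 108)
    de_fraction: float = 0.05
    effect_sizes: object = 2.0
    within_sd: float = 0.5
    baseline_law: str = "lognormal"
    ordering_pattern: object = "normal>nat>tumor"
    base_location: float = 1.0
    base_spread: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.group_sizes) != len(DEFAULT_GROUPS):
            raise ValueError(f"group_sizes must have {len(DEFAULT_GROUPS)} entries")
        if min(self.group_sizes) < 2:
            raise ValueError(f"each group needs >= 2 samples, got {self.group_sizes}")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if self.within_sd <= 0:
            raise ValueError("within_sd must be positive")
        if self.baseline_law not in ("lognormal", "normal"):
            raise ValueError(f"unknown baseline_law {self.baseline_law!r}")
        for pattern in self._patterns():
            if pattern not in _ORDERINGS:
                raise ValueError(
                    f"unknown ordering_pattern {pattern!r}; "
                    f"expected one of {sorted(_ORDERINGS)}"
                )

    @property
    def n_de(self) -> int:
        return round(self.de_fraction * self.n_genes)

    def _patterns(self) -> tuple:
        p = self.ordering_pattern
        return (p,) if isinstance(p, str) else tuple(p)

    def _effects(self) -> tuple:
        e = self.effect_sizes
        return (float(e),) if np.isscalar(e) else tuple(float(v) for v in e)


@dataclass(frozen=True)
class SimulationTruth:
    """Construction truth: DE gene ids, true per-group locations on the
    data scale, and the true thresholds between adjacent groups
    (ascending)."""

    de_gene_ids: tuple
    group_locations: dict = field(repr=False)
    thresholds: dict = field(repr=False)


def _gene_locations(spec: SimulationSpec, gene_index: int, base: float):
    """Per-group location parameters (latent scale) for one gene."""
    if gene_index >= spec.n_de:
        return {g: base for g in DEFAULT_GROUPS}
    patterns = spec._patterns()
    effects = spec._effects()
    pattern = patterns[gene_index % len(patterns)]
    effect = effects[gene_index % len(effects)]
    step = effect * spec.within_sd
    return {g: base + _ORDERINGS[pattern][g] * step for g in DEFAULT_GROUPS}


def simulate_expression(spec: SimulationSpec):
    """Draw a cohort from ``spec``.

    Returns ``(matrix, labels, truth)``: the genes × samples
    :class:`~mmdmarker.io.ExpressionMatrix`, the
    :class:`~mmdmarker.io.GroupLabels`, and the
    :class:`SimulationTruth`.
    """
    sizes = dict(zip(DEFAULT_GROUPS, spec.group_sizes))
    sample_ids, groups_per_sample = [], []
    for g in DEFAULT_GROUPS:
        for i in range(sizes[g]):
            sample_ids.append(f"{g}_{i + 1:03d}")
            groups_per_sample.append(g)
    labels = GroupLabels(dict(zip(sample_ids, groups_per_sample)))

    width = max(4, len(str(spec.n_genes)))
    gene_ids = [f"g{i + 1:0{width}d}" for i in range(spec.n_genes)]

    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_genes)
    values = np.empty((spec.n_genes, len(sample_ids)))
    group_locations, thresholds = {}, {}

    for i, gene in enumerate(gene_ids):
        rng = np.random.default_rng(streams[i])
        base = rng.normal(spec.base_location, spec.base_spread)
        latent_loc = _gene_locations(spec, i, base)
        latent = rng.normal(
            [latent_loc[g] for g in groups_per_sample], spec.within_sd
        )
        if spec.baseline_law == "lognormal":
            values[i] = np.exp(latent)
            to_data = np.exp
        else:
            values[i] = np.clip(latent, 0.0, None)
            to_data = float
        if i < spec.n_de:
            group_locations[gene] = {g: float(to_data(latent_loc[g])) for g in DEFAULT_GROUPS}
            ordered = sorted(latent_loc.values())
            thresholds[gene] = tuple(
                float(to_data((a + b) / 2.0)) for a, b in zip(ordered, ordered[1:])
            )

    matrix = ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)
    truth = SimulationTruth(
        de_gene_ids=tuple(gene_ids[: spec.n_de]),
        group_locations=group_locations,
        thresholds=thresholds,
    )
    return matrix, labels, truth


def default_paper_shape(seed: int = 0) -> SimulationSpec:
    """Desk-scale cohort echoing a realistic lung study's imbalance.

    Group sizes (75 normal, 12 NAT, 108 tumor) keep the field-typical
    ratio of a large cohort — many tumors, many normals, few paired NAT
    tissues — at a fifth of full scale; 500 genes with 5% DE at a
    2-within-sd adjacent-group shift.
    """
    return SimulationSpec(seed=seed)
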