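"""End-to-end marker-identification pipeline.

The framework has four stages: (1) score every gene on each pairwise
group comparison (MMD by default, optionally also the t-test and
fold-change baselines) and rank genes within each comparison; (2)
aggregate ranks into an average rank and select the top-k genes as
candidate markers; (3) export the candidate list for external
functional-enrichment tools; (4) identify the per-class expression
boundaries of the markers and evaluate the panel by cross-validated
tumor-vs-rest classification.

Every artifact is a deterministic function of the configuration, so a
rerun with the same config file reproduces the run byte-for-byte; the
manifest echoes the full configuration next to the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import scoring
from .boundaries import boundary_table
from .evaluation import CVConfig, cross_validate
from .io import (
    ExpressionMatrix,
    GroupLabels,
    log_transform,
    read_expression_table,
    read_labels,
    validate_pair,
)
from .mmd import KernelConfig
from .scoring import ComparisonSpec, DEFAULT_COMPARISONS, TUMOR_FOCUSED_PRESET

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger("mmdmarker")

#: average-rank presets by name
RANK_PRESETS = {
    "tumor_focused": scoring.TUMOR_FOCUSED_PRESET,
    "all_pairs": scoring.ALL_PAIRS_PRESET,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Complete configuration of one pipeline run."""

    matrix_path: str
    labels_path: str
    out_dir: str
    comparisons: tuple = DEFAULT_COMPARISONS
    methods: tuple = ("mmd",)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    rank_preset: str = "tumor_focused"
    rank_method: str = "mmd"
    top_k: int = 10
    cv: CVConfig = field(default_factory=CVConfig)
    log2_input: bool = False
    log2_offset: float = 1.0
    pseudocount: float = 0.0
    welch: bool = False
    delimiter: str = "\t"

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError(f"top_k must be >= 1, got {self.top_k}")
        if self.rank_preset not in RANK_PRESETS:
            raise ValueError(
                f"unknown rank_preset {self.rank_preset!r}; "
                f"expected one of {sorted(RANK_PRESETS)}"
            )
        if self.rank_method not in self.methods:
            raise ValueError(
                f"rank_method {self.rank_method!r} is not among methods {self.methods}"
            )


def load_config(path) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a JSON file.

    Nested objects use the same key names as the dataclasses:
    ``kernel`` maps to :class:`~mmdmarker.mmd.KernelConfig`, ``cv`` to
    :class:`~mmdmarker.evaluation.CVConfig`, and ``comparisons`` is a
    list of ``{"name":..., "group_a":..., "group_b":...}`` objects.
    """
    raw = json.loads(Path(path).read_text())
    if "comparisons" in raw:
        raw["comparisons"] = tuple(
            ComparisonSpec(**c) for c in raw["comparisons"]
        )
    if "methods" in raw:
        raw["methods"] = tuple(raw["methods"])
    if "kernel" in raw:
        raw["kernel"] = KernelConfig(**raw["kernel"])
    if "cv" in raw:
        raw["cv"] = CVConfig(**raw["cv"])
    return PipelineConfig(**raw)


def _config_manifest(config: PipelineConfig) -> dict:
    manifest = dataclasses.asdict(config)
    manifest["comparisons"] = [dataclasses.asdict(c) for c in config.comparisons]
    manifest["methods"] = list(config.methods)
    return manifest


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and write the artifacts into ``config.out_dir``.

    Returns a dict of artifact paths: ``scores``, ``ranks``,
    ``top_genes``, ``boundaries``, ``cv_report``, ``manifest``,
    ``run_log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        stage(f"load: reading matrix {config.matrix_path} and labels {config.labels_path}")
        matrix = read_expression_table(config.matrix_path, delimiter=config.delimiter)
        labels = read_labels(config.labels_path)
        validate_pair(matrix, labels)
        if config.log2_input:
            matrix = log_transform(matrix, config.log2_offset)
        stage(f"load: {matrix.n_genes} genes x {matrix.n_samples} samples")

        stage(f"score: methods={list(config.methods)} on "
              f"{[c.name for c in config.comparisons]}")
        table = scoring.score_table(
            matrix, labels,
            comparisons=config.comparisons,
            methods=config.methods,
            config=config.kernel,
            pseudocount=config.pseudocount,
            welch=config.welch,
        )
        scores_path = out / "scores.tsv"
        table.to_csv(scores_path, sep="\t", index=False, float_format="%.10g")

        stage(f"rank: preset {config.rank_preset} on method {config.rank_method}")
        preset = RANK_PRESETS[config.rank_preset]
        avg = scoring.average_rank(table, preset, method=config.rank_method)
        ranks_path = out / "average_ranks.tsv"
        avg.sort_values().rename_axis("gene_id").to_frame().to_csv(
            ranks_path, sep="\t", float_format="%.10g"
        )

        stage(f"select: top {config.top_k} genes by average rank")
        markers = scoring.top_k(avg, config.top_k)
        top_path = out / "top_genes.txt"
        top_path.write_text("".join(f"{g}\n" for g in markers))

        stage("boundary: per-class expression intervals for the markers")
        btable = boundary_table(matrix, labels, markers)
        boundaries_path = out / "boundaries.tsv"
        btable.to_csv(boundaries_path, sep="\t", index=False, float_format="%.10g")

        stage(f"evaluate: {config.cv.k}-fold CV, "
              f"{config.cv.positive_class}-vs-rest, seed {config.cv.seed}")
        metrics = cross_validate(matrix.restrict_genes(markers), labels, config.cv)
        cv_report = {
            "config": {
                "k": config.cv.k,
                "seed": config.cv.seed,
                "positive_class": config.cv.positive_class,
                "classifier": f"random_forest({config.cv.n_trees} trees)",
                "genes": list(markers),
            },
            "fold_counts": [dataclasses.asdict(c) for c in metrics.fold_counts],
            "per_fold": [dataclasses.asdict(m) for m in metrics.per_fold],
            "mean": {
                "recall": metrics.recall,
                "f1": metrics.f1,
                "accuracy": metrics.accuracy,
                "mcc": metrics.mcc,
            },
            "pooled": dataclasses.asdict(metrics.pooled),
        }
        cv_path = out / "cv_report.json"
        cv_path.write_text(json.dumps(cv_report, indent=2) + "\n")

        manifest_path = out / "manifest.json"
        manifest_path.write_text(
            json.dumps({"config": _config_manifest(config)}, indent=2) + "\n"
        )
        run_log_path = out / "run.log"
        run_log_path.write_text("".join(f"{line}\n" for line in log_lines))
    except Exception as exc:
        stage_name = log_lines[-1].split(":", 1)[0] if log_lines else "load"
        raise RuntimeError(f"pipeline failed at stage {stage_name!r}: {exc}") from exc

    return {
        "scores": scores_path,
        "ranks": ranks_path,
        "top_genes": top_path,
        "boundaries": boundaries_path,
        "cv_report": cv_path,
        "manifest": manifest_path,
        "run_log": run_log_path,
    }
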