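"""End-to-end orchestration: classification -> differential expression ->
guide network -> modules -> bait-prey fishing -> enrichment.

Mirrors the analysis chain of a two-condition root RNA-seq contrast: genes
are tiered and tested for differential expression, the differentially
expressed genes become the guide list for co-expression network
construction over a normalized compendium, connected components of that
network are reported as modules, a bait module is combined with a prey pool
for fishing, and gene sets of interest are tested for term enrichment.

Every stage writes plain TSV/JSON under the output directory and the run
report records counts that can be recomputed from those files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as cio
from .enrichment import enrich, enrichment_to_frame
from .expression import (
    ClassificationThresholds,
    classify_all,
    de_records_to_frame,
    differential_expression,
)
from .network import (
    build_bait_prey_network,
    build_guide_network,
    find_modules,
    fished_preys,
    network_summary,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for one pipeline run.

    ``guides``, ``baits``, ``preys`` and ``annotation`` are optional: without
    a guide list the differentially expressed genes are used as guides,
    without baits the largest module serves as the bait set, and the fishing
    and enrichment stages are skipped when their inputs are absent.
    """

    counts: str
    sample_map: str
    compendium: str
    outdir: str
    guides: str | None = None
    baits: str | None = None
    preys: str | None = None
    annotation: str | None = None
    cond_treat: str = "-Pi"
    cond_ref: str = "+Pi"
    low_max: int = 10
    high_min: int = 2000
    r_threshold: float = 0.7
    de_alpha: float = 0.05
    enrich_alpha: float = 0.01
    absolute_r: bool = False
    welch: bool = False
    bh_correction: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        ClassificationThresholds(self.low_max, self.high_min)  # validates
        if not (0 < self.r_threshold <= 1):
            raise ValueError(f"r_threshold must be in (0, 1], got {self.r_threshold}")
        for name in ("de_alpha", "enrich_alpha"):
            value = getattr(self, name)
            if not (0 < value < 1):
                raise ValueError(f"{name} must be in (0, 1), got {value}")
        for name in ("counts", "sample_map", "compendium", "guides", "baits", "preys", "annotation"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"config field {name!r}: no such file: {path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: pipeline config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config fields {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunReport:
    """Per-stage bookkeeping for one run; every count is recomputable from
    the files the run wrote."""

    stages: dict[str, dict] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    input_hashes: dict[str, str] = field(default_factory=dict)
    wall_clock_s: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "skipped": self.skipped,
                "input_hashes": self.input_hashes,
                "wall_clock_s": self.wall_clock_s,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


class _StageTimer:
    def __init__(self, report: RunReport, stage: str):
        self.report = report
        self.stage = stage

    def __enter__(self):
        logger.info("=== stage: %s ===", self.stage)
        self._t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        self.report.wall_clock_s[self.stage] = round(time.perf_counter() - self._t0, 6)
        if exc is not None:
            logger.error("stage %s failed: %s", self.stage, exc)
        return False


def _direction_tags(records) -> dict[str, str]:
    tags: dict[str, str] = {}
    for rec in records:
        if rec.de_novo:
            tags[rec.gene_id] = "up"
        elif rec.significant and rec.ratio is not None:
            tags[rec.gene_id] = "up" if rec.ratio > 1 else "down"
        else:
            tags[rec.gene_id] = "unchanged"
    return tags


def _export_all(graph, outdir: Path, stem: str) -> None:
    for fmt, suffix in (("sif", ".sif"), ("graphml", ".graphml"), ("tsv", ".edges.tsv")):
        cio.export_network(graph, outdir / f"{stem}{suffix}", fmt)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every configured stage; returns the report (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    for name in ("counts", "sample_map", "compendium", "guides", "baits", "preys", "annotation"):
        path = getattr(config, name)
        if path is not None:
            report.input_hashes[name] = _sha256(path)

    with _StageTimer(report, "load"):
        matrix = cio.read_counts(config.counts, config.sample_map)
        compendium = cio.read_compendium(config.compendium)
        report.stages["load"] = {
            "n_genes": len(matrix.gene_ids),
            "n_samples": len(matrix.sample_ids),
            "compendium_samples": compendium.n_samples,
            "compendium_genes": len(compendium.gene_ids),
        }

    thresholds = ClassificationThresholds(config.low_max, config.high_min)
    with _StageTimer(report, "classify"):
        table = classify_all(matrix, config.cond_ref, thresholds)
        table.to_frame().to_csv(outdir / "expression_classes.tsv", sep="\t", index=False)
        tier_counts = {cls.value: count for cls, count in table.counts.items()}
        (outdir / "expression_classes_summary.json").write_text(
            json.dumps(tier_counts, indent=2, sort_keys=True) + "\n"
        )
        report.stages["classify"] = {"condition": config.cond_ref, "tier_counts": tier_counts}

    with _StageTimer(report, "diffexp"):
        records = differential_expression(
            matrix,
            config.cond_treat,
            config.cond_ref,
            alpha=config.de_alpha,
            welch=config.welch,
            bh_correction=config.bh_correction,
        )
        de_records_to_frame(records).to_csv(
            outdir / "differential_expression.tsv", sep="\t", index=False, float_format="%.6g"
        )
        de_genes = sorted(r.gene_id for r in records if r.significant or r.de_novo)
        n_de_novo = sum(r.de_novo for r in records)
        report.stages["diffexp"] = {
            "n_tested": len(records),
            "n_significant": sum(r.significant for r in records),
            "n_de_novo": n_de_novo,
            "n_de_genes": len(de_genes),
        }

    if config.guides is not None:
        guides = cio.read_gene_list(config.guides)
    else:
        guides = de_genes
        logger.info("no guide list configured; using the %d DE genes as guides", len(guides))
    cio.write_gene_list(guides, outdir / "guide_genes.txt")
    direction = _direction_tags(records)

    with _StageTimer(report, "network"):
        guide_net = build_guide_network(
            compendium, guides, config.r_threshold, absolute=config.absolute_r
        )
        for node in guide_net.nodes:
            guide_net.nodes[node]["direction_tag"] = direction.get(node, "unchanged")
        _export_all(guide_net, outdir, "guide_network")
        summary = network_summary(guide_net)
        report.stages["network"] = {
            "n_guides_in": len(guides),
            "n_nodes": summary["n_nodes"],
            "n_edges": summary["n_edges"],
        }

    with _StageTimer(report, "modules"):
        modules = find_modules(guide_net)
        with open(outdir / "modules.tsv", "w") as handle:
            handle.write("module_id\tgene_id\n")
            for idx, module in enumerate(modules, start=1):
                for gene in sorted(module):
                    handle.write(f"module_{idx}\t{gene}\n")
        report.stages["modules"] = {
            "n_modules": len(modules),
            "module_sizes": [len(m) for m in modules],
        }

    fished: list[str] = []
    bait_net = None
    if config.preys is not None:
        with _StageTimer(report, "fish"):
            preys = cio.read_gene_list(config.preys)
            if config.baits is not None:
                baits = cio.read_gene_list(config.baits)
            elif modules:
                baits = sorted(modules[0])
                logger.info("no bait list configured; using the largest module (%d genes)", len(baits))
            else:
                raise ValueError("fishing stage: no bait list and no module to use as baits")
            bait_net = build_bait_prey_network(
                compendium, baits, preys, config.r_threshold, absolute=config.absolute_r
            )
            for node in bait_net.nodes:
                bait_net.nodes[node]["direction_tag"] = direction.get(node, "unchanged")
            _export_all(bait_net, outdir, "bait_prey_network")
            fished = fished_preys(bait_net)
            cio.write_gene_list(fished, outdir / "fished_genes.txt")
            summary = network_summary(bait_net)
            report.stages["fish"] = {
                "n_baits_in": len(baits),
                "n_preys_in": len(preys),
                "n_nodes": summary["n_nodes"],
                "n_edges": summary["n_edges"],
                "n_bait_nodes": summary["nodes_by_role"].get("bait", 0),
                "n_fished": len(fished),
            }
    else:
        report.skipped.append("fish")
        logger.info("fishing stage skipped: no prey list configured")

    if config.annotation is not None:
        with _StageTimer(report, "enrich"):
            annotation = cio.read_annotation(config.annotation)
            queries = {"network": set(guide_net.nodes)}
            if fished:
                queries["fished"] = set(fished)
            stage: dict[str, dict] = {}
            for name, query in queries.items():
                restricted = query & annotation.background
                if not restricted:
                    logger.warning("enrichment query %r empty after background restriction", name)
                    stage[name] = {"n_query": 0, "n_terms_tested": 0, "n_enriched": 0}
                    continue
                results = enrich(
                    restricted,
                    annotation,
                    alpha=config.enrich_alpha,
                    bh_correction=config.bh_correction,
                )
                enrichment_to_frame(results).to_csv(
                    outdir / f"enrichment_{name}.tsv", sep="\t", index=False, float_format="%.6g"
                )
                stage[name] = {
                    "n_query": len(restricted),
                    "n_terms_tested": len(results),
                    "n_enriched": sum(r.enriched for r in results),
                }
            report.stages["enrich"] = stage
    else:
        report.skipped.append("enrich")
        logger.info("enrichment stage skipped: no annotation configured")

    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
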