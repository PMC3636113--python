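"""Seeded generators for replicate count tables, expression compendia and
annotations, with the planted ground truth returned alongside every dataset.

Counts are negative-binomial per gene with tier-specific means (mean/
dispersion parameterization, variance = mu + dispersion * mu^2), emulating a
two-condition RNA-seq design with a small number of biological replicates.
Differentially expressed genes multiply the treatment mean by a fold change;
"de novo" genes are silent in the reference condition and expressed under
treatment.  Reference-condition draws are nudged into their planted tier
bracket so the planted tier labels are exactly recoverable by the
classifier.

The compendium generator plants rank-1 co-expression blocks: every gene of a
module loads on one shared latent factor per sample, value = w * z + eps,
which gives the closed-form expected within-module correlation
w^2 s_z^2 / (w^2 s_z^2 + s_eps^2).

Annotations plant one term concentrated on a designated gene set among
uniformly random filler terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .expression import ClassificationThresholds, ExpressionClass, ReadCountMatrix
from .network import ExpressionCompendium

__all__ = [
    "CountSimConfig",
    "CompendiumSimConfig",
    "SyntheticTruth",
    "simulate_counts",
    "simulate_compendium",
    "simulate_annotation",
    "loading_for_correlation",
    "expected_module_correlation",
    "tiny_dataset",
    "paper_scale_dataset",
    "write_dataset",
]

TIER_ORDER = (
    ExpressionClass.NOT_EXPRESSED,
    ExpressionClass.LOW,
    ExpressionClass.MEDIUM,
    ExpressionClass.HIGH,
)


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted next to every simulated dataset."""

    tiers: dict[str, str] = field(default_factory=dict)
    de_genes: list[str] = field(default_factory=list)
    de_down_genes: list[str] = field(default_factory=list)
    de_novo_genes: list[str] = field(default_factory=list)
    modules: dict[str, list[str]] = field(default_factory=dict)
    expected_within_module_r: float | None = None
    planted_term: str | None = None
    planted_term_genes: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class CountSimConfig:
    """Design of a simulated two-condition replicate count experiment.

    Tier fractions follow the observed composition of a root kinase/
    phosphatase transcriptome (a small silent fraction, a similar low
    fraction, a dominant medium tier and a few percent of very abundant
    genes); tier means are on the raw unique-read scale.  ``de_fraction`` is
    the fraction of all genes planted as differentially expressed (drawn from
    the medium tier), of which ``down_fraction`` are repressed instead of
    induced; ``de_novo_fraction`` genes are planted silent in the reference
    and expressed under treatment.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    tier_fractions: tuple[float, float, float, float] = (0.08, 0.09, 0.78, 0.05)
    tier_means: tuple[float, float, float, float] = (0.0, 3.0, 200.0, 5000.0)
    dispersion: float = 0.1
    de_fraction: float = 0.15
    down_fraction: float = 0.1
    fold_change: float = 8.0
    de_novo_fraction: float = 0.01
    cond_ref: str = "+Pi"
    cond_treat: str = "-Pi"
    thresholds: ClassificationThresholds = ClassificationThresholds()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_replicates < 1:
            raise ValueError("n_genes and n_replicates must be positive")
        fr = self.tier_fractions
        if len(fr) != 4 or any(f < 0 or f > 1 for f in fr) or not math.isclose(sum(fr), 1.0):
            raise ValueError(f"tier fractions must lie in [0,1] and sum to 1, got {fr}")
        if any(f < 0 or f > 1 for f in (self.de_fraction, self.de_novo_fraction, self.down_fraction)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        if self.fold_change <= 1:
            raise ValueError(f"fold change must be > 1, got {self.fold_change}")
        if self.tier_means[0] != 0:
            raise ValueError("the not-expressed tier mean must be 0")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial with variance mean + dispersion*mean^2."""
    if mean == 0:
        return np.zeros(size, dtype=np.int64)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size).astype(np.int64)


def _tier_bracket(tier: ExpressionClass, th: ClassificationThresholds) -> tuple[int, int | None]:
    """Required range of the maximum replicate count for a tier."""
    if tier is ExpressionClass.NOT_EXPRESSED:
        return 0, 0
    if tier is ExpressionClass.LOW:
        return 1, th.low_max
    if tier is ExpressionClass.MEDIUM:
        return th.low_max + 1, th.high_min
    return th.high_min + 1, None


def _enforce_tier(row: np.ndarray, tier: ExpressionClass, th: ClassificationThresholds) -> np.ndarray:
    """Nudge one gene's replicate counts so its maximum lands in the tier bracket."""
    lo, hi = _tier_bracket(tier, th)
    row = row.copy()
    if hi is not None:
        np.minimum(row, hi, out=row)
    if row.max() < lo:
        row[int(np.argmax(row))] = lo
    return row


def _largest_remainder(fractions: tuple[float, ...], total: int) -> list[int]:
    raw = [f * total for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainder = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def simulate_counts(config: CountSimConfig) -> tuple[ReadCountMatrix, SyntheticTruth]:
    """Draw a replicate-by-gene count table for two conditions plus its truth."""
    rng = np.random.default_rng(config.seed)
    th = config.thresholds
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(n)]

    tier_counts = _largest_remainder(config.tier_fractions, n)
    tier_of = np.repeat(np.arange(4), tier_counts)
    rng.shuffle(tier_of)
    tiers = {g: TIER_ORDER[t] for g, t in zip(genes, tier_of)}

    medium_pool = [g for g in genes if tiers[g] is ExpressionClass.MEDIUM]
    silent_pool = [g for g in genes if tiers[g] is ExpressionClass.NOT_EXPRESSED]
    n_de = min(int(round(config.de_fraction * n)), len(medium_pool))
    n_dn = min(int(round(config.de_novo_fraction * n)), len(silent_pool))
    de_genes = sorted(map(str, rng.choice(medium_pool, size=n_de, replace=False))) if n_de else []
    n_down = int(round(config.down_fraction * n_de))
    de_down = sorted(map(str, rng.choice(de_genes, size=n_down, replace=False))) if n_down else []
    de_novo = sorted(map(str, rng.choice(silent_pool, size=n_dn, replace=False))) if n_dn else []
    de_set, down_set, dn_set = set(de_genes), set(de_down), set(de_novo)

    reps = config.n_replicates
    ref = np.zeros((n, reps), dtype=np.int64)
    treat = np.zeros((n, reps), dtype=np.int64)
    medium_mean = config.tier_means[2]
    for i, g in enumerate(genes):
        tier = tiers[g]
        mean = config.tier_means[tier_of[i]]
        ref_row = _enforce_tier(_nb_draw(rng, mean, config.dispersion, reps), tier, th)
        if g in dn_set:
            row = _nb_draw(rng, medium_mean, config.dispersion, reps)
            if row.max() == 0:
                row[0] = 1  # a de novo transcript must be seen at least once
            treat_row = row
        elif g in de_set:
            fc = 1.0 / config.fold_change if g in down_set else config.fold_change
            treat_row = _nb_draw(rng, mean * fc, config.dispersion, reps)
        else:
            treat_row = _enforce_tier(_nb_draw(rng, mean, config.dispersion, reps), tier, th)
        ref[i] = ref_row
        treat[i] = treat_row

    ref_samples = [f"{config.cond_ref}_r{j + 1}" for j in range(reps)]
    treat_samples = [f"{config.cond_treat}_r{j + 1}" for j in range(reps)]
    counts = pd.DataFrame(
        np.hstack([ref, treat]), index=genes, columns=ref_samples + treat_samples
    )
    conditions = pd.Series(
        {**{s: config.cond_ref for s in ref_samples}, **{s: config.cond_treat for s in treat_samples}}
    )
    matrix = ReadCountMatrix(counts=counts, conditions=conditions)
    truth = SyntheticTruth(
        tiers={g: tiers[g].value for g in genes},
        de_genes=list(de_genes),
        de_down_genes=list(de_down),
        de_novo_genes=list(de_novo),
        config={"kind": "counts", **_config_echo(config)},
    )
    return matrix, truth


def _config_echo(config) -> dict:
    echo = asdict(config)
    th = echo.get("thresholds")
    if th is not None:
        echo["thresholds"] = dict(th)
    return echo


def expected_module_correlation(w: float, sigma_z: float, sigma_eps: float) -> float:
    """Within-module correlation implied by the rank-1 factor model."""
    signal = w * w * sigma_z * sigma_z
    return signal / (signal + sigma_eps * sigma_eps)


def loading_for_correlation(r: float, sigma_z: float = 1.0, sigma_eps: float = 1.0) -> float:
    """Factor loading w giving expected within-module correlation r."""
    if not (0 < r < 1):
        raise ValueError(f"target correlation must be in (0, 1), got {r}")
    return (sigma_eps / sigma_z) * math.sqrt(r / (1.0 - r))


@dataclass(frozen=True)
class CompendiumSimConfig:
    """Design of a simulated expression compendium with planted modules.

    The default 300 samples mirror a root-focused microarray compendium.
    Either fix the loading ``w`` directly or give ``target_r``, the desired
    expected within-module correlation, from which ``w`` is derived.
    """

    n_samples: int = 300
    module_sizes: tuple[int, ...] = (10, 10, 10)
    n_background: int = 50
    w: float | None = None
    target_r: float = 0.9
    sigma_z: float = 1.0
    sigma_eps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3:
            raise ValueError("need at least 3 samples")
        if any(s < 1 for s in self.module_sizes) or self.n_background < 0:
            raise ValueError("module sizes must be positive and background non-negative")
        if self.sigma_z <= 0 or self.sigma_eps < 0:
            raise ValueError("sigma_z must be > 0 and sigma_eps >= 0")
        if self.w is None and not (0 < self.target_r < 1):
            raise ValueError(f"target_r must be in (0, 1), got {self.target_r}")

    @property
    def loading(self) -> float:
        if self.w is not None:
            return self.w
        return loading_for_correlation(self.target_r, self.sigma_z, self.sigma_eps)


def simulate_compendium(
    config: CompendiumSimConfig,
    module_members: dict[str, list[str]] | None = None,
    background_genes: list[str] | None = None,
) -> tuple[ExpressionCompendium, SyntheticTruth]:
    """Samples x genes compendium with rank-1 planted modules plus its truth.

    By default genes are named ``M<k>_G<j>`` (module members) and ``BG<j>``
    (background); explicit ``module_members``/``background_genes`` override
    the naming and sizes so modules can be planted on externally chosen ids.
    """
    rng = np.random.default_rng(config.seed)
    if module_members is None:
        module_members = {
            f"module_{k + 1}": [f"M{k + 1}_G{j + 1:03d}" for j in range(size)]
            for k, size in enumerate(config.module_sizes)
        }
    if background_genes is None:
        background_genes = [f"BG{j + 1:04d}" for j in range(config.n_background)]
    all_module_genes = [g for genes in module_members.values() for g in genes]
    if len(set(all_module_genes)) != len(all_module_genes):
        raise ValueError("a gene may belong to at most one planted module")
    overlap = set(all_module_genes) & set(background_genes)
    if overlap:
        raise ValueError(f"genes both in a module and background: {sorted(overlap)[:10]}")

    w = config.loading
    n = config.n_samples
    columns: dict[str, np.ndarray] = {}
    for name in module_members:
        z = rng.normal(0.0, config.sigma_z, size=n)
        for g in module_members[name]:
            columns[g] = w * z + rng.normal(0.0, config.sigma_eps, size=n)
    for g in background_genes:
        columns[g] = rng.normal(0.0, math.hypot(w * config.sigma_z, config.sigma_eps), size=n)

    samples = [f"S{i + 1:04d}" for i in range(n)]
    frame = pd.DataFrame(columns, index=samples)
    compendium = ExpressionCompendium(values=frame)
    truth = SyntheticTruth(
        modules={name: list(genes) for name, genes in module_members.items()},
        expected_within_module_r=expected_module_correlation(
            w, config.sigma_z, config.sigma_eps
        ),
        config={"kind": "compendium", **_config_echo(config)},
    )
    return compendium, truth


def simulate_annotation(
    n_genes: int,
    n_terms: int,
    planted_term_size: int,
    seed: int,
    *,
    gene_ids: list[str] | None = None,
    planted_genes: list[str] | None = None,
    filler_term_size: int = 10,
) -> tuple[AnnotationTable, SyntheticTruth]:
    """Annotation table with one planted term over a designated gene set.

    The remaining ``n_terms - 1`` filler terms annotate uniformly random
    genes.  ``planted_genes`` pins the planted gene set; otherwise the first
    ``planted_term_size`` genes carry it.
    """
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    if len(gene_ids) != n_genes:
        raise ValueError(f"gene_ids has {len(gene_ids)} entries, expected {n_genes}")
    if planted_term_size > n_genes:
        raise ValueError("planted term size exceeds the gene universe")
    if n_terms < 1:
        raise ValueError("need at least the planted term")
    rng = np.random.default_rng(seed)
    if planted_genes is None:
        planted_genes = gene_ids[:planted_term_size]
    else:
        stray = set(planted_genes) - set(gene_ids)
        if stray:
            raise ValueError(f"planted genes outside the universe: {sorted(stray)[:10]}")
    planted_term = "T0000_planted"
    pairs: list[tuple[str, str]] = [(g, planted_term) for g in planted_genes]
    size = min(filler_term_size, n_genes)
    for t in range(1, n_terms):
        members = rng.choice(gene_ids, size=size, replace=False)
        pairs.extend((g, f"T{t:04d}") for g in members)
    table = AnnotationTable.from_pairs(pairs, background=set(gene_ids))
    truth = SyntheticTruth(
        planted_term=planted_term,
        planted_term_genes=list(planted_genes),
        config={
            "kind": "annotation",
            "n_genes": n_genes,
            "n_terms": n_terms,
            "planted_term_size": len(planted_genes),
            "filler_term_size": filler_term_size,
            "seed": seed,
        },
    )
    return table, truth


@dataclass
class DatasetBundle:
    """All inputs for an end-to-end run plus the merged planted truth."""

    counts: ReadCountMatrix
    compendium: ExpressionCompendium
    guides: list[str]
    baits: list[str]
    preys: list[str]
    annotation: AnnotationTable
    truth: SyntheticTruth


def _build_bundle(
    count_config: CountSimConfig,
    *,
    n_samples: int,
    module_plan: list[int],
    n_preys: int,
    n_fished: int,
    n_terms: int,
    target_r: float,
    seed: int,
) -> DatasetBundle:
    """Assemble counts, a matching compendium, gene lists and an annotation.

    Co-expression modules are planted on differentially expressed genes (the
    guide list downstream), the first (largest) module doubling as the bait
    set; ``n_fished`` of the prey genes share that module's latent factor so
    they are recoverable by fishing.
    """
    rng = np.random.default_rng(seed)
    matrix, truth = simulate_counts(count_config)
    guides = sorted(set(truth.de_genes) | set(truth.de_novo_genes))
    if sum(module_plan) > len(guides):
        raise ValueError("module plan larger than the planted DE gene set")

    picked = [str(g) for g in rng.choice(guides, size=sum(module_plan), replace=False)]
    modules: dict[str, list[str]] = {}
    start = 0
    for k, size in enumerate(module_plan):
        modules[f"module_{k + 1}"] = sorted(picked[start : start + size])
        start += size
    baits = modules["module_1"]

    preys = [f"P{j + 1:04d}" for j in range(n_preys)]
    fished = preys[:n_fished]
    # Fished preys ride the bait module's latent factor, so fishing recovers them.
    plant = {name: list(genes) for name, genes in modules.items()}
    plant["module_1"] = sorted(set(plant["module_1"]) | set(fished))

    module_gene_set = {g for genes in plant.values() for g in genes}
    background = [g for g in matrix.gene_ids if g not in module_gene_set]
    background += [p for p in preys if p not in module_gene_set]

    comp_config = CompendiumSimConfig(
        n_samples=n_samples,
        module_sizes=tuple(len(v) for v in plant.values()),
        n_background=len(background),
        target_r=target_r,
        seed=seed + 1,
    )
    compendium, comp_truth = simulate_compendium(
        comp_config, module_members=plant, background_genes=background
    )

    universe = list(matrix.gene_ids) + preys
    annotation, ann_truth = simulate_annotation(
        n_genes=len(universe),
        n_terms=n_terms,
        planted_term_size=len(baits) + len(fished),
        seed=seed + 2,
        gene_ids=universe,
        planted_genes=sorted(set(baits) | set(fished)),
    )

    truth.modules = comp_truth.modules
    truth.expected_within_module_r = comp_truth.expected_within_module_r
    truth.planted_term = ann_truth.planted_term
    truth.planted_term_genes = ann_truth.planted_term_genes
    truth.config = {
        "kind": "bundle",
        "counts": truth.config,
        "compendium": comp_truth.config,
        "annotation": ann_truth.config,
        "seed": seed,
    }
    return DatasetBundle(
        counts=matrix,
        compendium=compendium,
        guides=guides,
        baits=baits,
        preys=preys,
        annotation=annotation,
        truth=truth,
    )


def tiny_dataset(seed: int = 0) -> DatasetBundle:
    """Small preset for fast end-to-end checks (tens of genes)."""
    config = CountSimConfig(
        n_genes=30,
        tier_fractions=(0.1, 0.1, 0.7, 0.1),
        de_fraction=0.5,
        de_novo_fraction=0.1,
        seed=seed,
    )
    return _build_bundle(
        config,
        n_samples=60,
        module_plan=[6, 4],
        n_preys=10,
        n_fished=5,
        n_terms=5,
        target_r=0.9,
        seed=seed,
    )


def paper_scale_dataset(seed: int = 0) -> DatasetBundle:
    """Preset mirroring the study's scale: roughly 200 differentially
    expressed guide genes, a 22-gene bait module, 208 prey genes and a
    300-sample compendium."""
    config = CountSimConfig(
        n_genes=1323,
        de_fraction=0.145,
        de_novo_fraction=0.01,
        seed=seed,
    )
    return _build_bundle(
        config,
        n_samples=300,
        module_plan=[22, 12, 8],
        n_preys=208,
        n_fished=75,
        n_terms=40,
        target_r=0.85,
        seed=seed,
    )


def write_dataset(bundle: DatasetBundle, outdir) -> dict[str, str]:
    """Write a bundle in the TSV/text formats the pipeline reads.

    Returns a name -> path map covering every written file, including the
    truth JSON.
    """
    from . import io as cio  # local import to avoid a cycle at import time
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "sample_map": out / "samples.tsv",
        "compendium": out / "compendium.tsv",
        "guides": out / "guides.txt",
        "baits": out / "baits.txt",
        "preys": out / "preys.txt",
        "annotation": out / "annotation.tsv",
        "truth": out / "truth.json",
    }
    cio.write_counts(bundle.counts, paths["counts"], paths["sample_map"])
    cio.write_compendium(bundle.compendium, paths["compendium"])
    cio.write_gene_list(bundle.guides, paths["guides"])
    cio.write_gene_list(bundle.baits, paths["baits"])
    cio.write_gene_list(bundle.preys, paths["preys"])
    cio.write_annotation(bundle.annotation, paths["annotation"])
    paths["truth"].write_text(bundle.truth.to_json() + "\n")
    return {k: str(v) for k, v in paths.items()}
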