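"""Tiered expression classification and differential expression from replicate counts.

Genes are binned into four abundance tiers from unique-read counts taken over
biological replicates of a single condition: not expressed (zero in every
replicate), low (maximum replicate count at or below ``low_max``), high
(maximum above ``high_min``), and medium otherwise.  Classifying on the
maximum replicate makes the four tiers a mutually exclusive, exhaustive
partition of any gene set.

Differential expression between two conditions is called per gene with a
two-sample Student t-test on log2(counts-per-million + 1), and condition
ratios are reported alongside, including "de novo synthesis" calls for
transcripts absent in the reference condition but present under treatment.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionClass",
    "ClassificationThresholds",
    "ReadCountMatrix",
    "ExpressionClassTable",
    "DifferentialExpressionRecord",
    "normalize_counts",
    "classify_expression",
    "classify_all",
    "differential_expression",
    "expression_ratio",
]

CPM_SCALE = 1e6


class ExpressionClass(enum.Enum):
    """Abundance tier of a gene under one condition."""

    NOT_EXPRESSED = "NOT_EXPRESSED"
    LOW = "LOW"
    MEDIUM = "MEDIUM"
    HIGH = "HIGH"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


@dataclass(frozen=True)
class ClassificationThresholds:
    """Count cutoffs for the abundance tiers.

    ``low_max`` is the largest maximum-replicate count still called LOW
    (default 10 unique reads); ``high_min`` is the smallest count above which
    a gene is called HIGH (default 2000 unique reads).
    """

    low_max: int = 10
    high_min: int = 2000

    def __post_init__(self) -> None:
        if not (0 < self.low_max < self.high_min):
            raise ValueError(
                f"thresholds must satisfy 0 < low_max < high_min, "
                f"got low_max={self.low_max}, high_min={self.high_min}"
            )


@dataclass
class ReadCountMatrix:
    """Replicate unique-read counts per gene under labeled conditions.

    Parameters
    ----------
    counts
        Genes x samples table of non-negative integers.  The index holds
        gene ids, the columns sample ids.
    conditions
        Map from sample id to condition label (e.g. ``"+Pi"`` / ``"-Pi"``),
        covering every sample column exactly once.
    """

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if not isinstance(self.conditions, pd.Series):
            self.conditions = pd.Series(dict(self.conditions))
        missing = [s for s in self.counts.columns if s not in self.conditions.index]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        self.conditions = self.conditions.loc[list(self.counts.columns)]
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(values < 0):
                raise ValueError("counts must be non-negative")
            if not np.all(np.equal(np.mod(values, 1), 0)):
                raise ValueError("counts must be integer-valued")
        self.counts = self.counts.astype(np.int64)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def condition_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.conditions:
            seen.setdefault(c, None)
        return list(seen)

    def samples_for(self, condition: str) -> list[str]:
        samples = [s for s in self.counts.columns if self.conditions[s] == condition]
        if not samples:
            raise KeyError(
                f"unknown condition {condition!r}; available: {self.condition_labels()}"
            )
        return samples


@dataclass
class ExpressionClassTable:
    """Per-gene abundance tier plus the per-tier tallies."""

    classes: pd.Series  # gene id -> ExpressionClass
    counts: dict[ExpressionClass, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.classes.index, "expression_class": [c.value for c in self.classes]}
        )


@dataclass
class DifferentialExpressionRecord:
    """Per-gene result of the two-condition contrast.

    ``ratio`` is mean(treatment CPM) / mean(reference CPM) when the reference
    mean is positive; ``de_novo`` marks transcripts with zero reads in every
    reference replicate but at least one treatment read (the ratio is then
    reported as infinite); both ``ratio`` and ``p_value`` are ``None``
    (undefined) when no signal exists to compare.  ``ratio_mean``/``ratio_sd``
    summarise per-replicate-pair ratios (paired by replicate index) and are
    only defined when every reference replicate is positive and the replicate
    numbers match.
    """

    gene_id: str
    p_value: float | None
    ratio: float | None
    de_novo: bool
    ratio_mean: float | None
    ratio_sd: float | None
    significant: bool
    corrected_p: float | None = None

    @property
    def undefined_ratio(self) -> bool:
        return self.ratio is None and not self.de_novo


def normalize_counts(matrix: ReadCountMatrix) -> pd.DataFrame:
    """Scale each sample to counts per million; every column sums to 1e6."""
    totals = matrix.counts.sum(axis=0)
    zero = [str(s) for s in totals.index[totals == 0]]
    if zero:
        raise ValueError(f"cannot normalize samples with zero total count: {zero}")
    return matrix.counts / totals * CPM_SCALE


def _check_replicates(replicate_counts) -> np.ndarray:
    values = np.asarray(replicate_counts)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("need a 1-d array of at least one replicate count")
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("replicate counts must be numeric")
    if np.any(values < 0) or not np.all(np.equal(np.mod(values, 1), 0)):
        raise ValueError(f"replicate counts must be non-negative integers: {values!r}")
    return values.astype(np.int64)


def classify_expression(
    replicate_counts, thresholds: ClassificationThresholds = ClassificationThresholds()
) -> ExpressionClass:
    """Assign one abundance tier from a gene's replicate counts.

    The tier depends only on the multiset of counts (through the maximum):
    all-zero -> NOT_EXPRESSED; max <= low_max -> LOW; max > high_min -> HIGH;
    otherwise MEDIUM.
    """
    values = _check_replicates(replicate_counts)
    top = int(values.max())
    if top == 0:
        return ExpressionClass.NOT_EXPRESSED
    if top <= thresholds.low_max:
        return ExpressionClass.LOW
    if top > thresholds.high_min:
        return ExpressionClass.HIGH
    return ExpressionClass.MEDIUM


def classify_all(
    matrix: ReadCountMatrix,
    condition: str,
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ExpressionClassTable:
    """Classify every gene from its replicate counts under one condition."""
    samples = matrix.samples_for(condition)
    sub = matrix.counts[samples].to_numpy()
    classes = [classify_expression(row, thresholds) for row in sub]
    series = pd.Series(classes, index=matrix.counts.index, dtype=object)
    tallies = {cls: 0 for cls in ExpressionClass}
    for cls in classes:
        tallies[cls] += 1
    return ExpressionClassTable(classes=series, counts=tallies)


def _pair_ratio_summary(
    treat_norm: np.ndarray, ref_norm: np.ndarray
) -> tuple[float | None, float | None]:
    # Per-replicate-pair ratios need a bijection between replicates; pair by
    # index and only when every reference replicate is positive.
    if treat_norm.size != ref_norm.size or np.any(ref_norm <= 0):
        return None, None
    ratios = treat_norm / ref_norm
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else None
    return mean, sd


def expression_ratio(
    gene_id: str,
    matrix: ReadCountMatrix,
    cond_treat: str,
    cond_ref: str,
    normalized: pd.DataFrame | None = None,
) -> DifferentialExpressionRecord:
    """Condition ratio for one gene, with de novo and undefined handling.

    Passing a precomputed ``normalize_counts`` result avoids renormalizing
    when ratios for many genes are needed.
    """
    if gene_id not in matrix.counts.index:
        raise KeyError(f"unknown gene id {gene_id!r}")
    if normalized is None:
        normalized = normalize_counts(matrix)
    treat_samples = matrix.samples_for(cond_treat)
    ref_samples = matrix.samples_for(cond_ref)
    raw_treat = matrix.counts.loc[gene_id, treat_samples].to_numpy()
    raw_ref = matrix.counts.loc[gene_id, ref_samples].to_numpy()
    norm_treat = normalized.loc[gene_id, treat_samples].to_numpy(dtype=float)
    norm_ref = normalized.loc[gene_id, ref_samples].to_numpy(dtype=float)

    if np.all(raw_ref == 0):
        if np.all(raw_treat == 0):
            return DifferentialExpressionRecord(
                gene_id, None, None, False, None, None, False
            )
        return DifferentialExpressionRecord(gene_id, None, None, True, None, None, False)
    ratio = float(np.mean(norm_treat) / np.mean(norm_ref))
    mean, sd = _pair_ratio_summary(norm_treat, norm_ref)
    return DifferentialExpressionRecord(gene_id, None, ratio, False, mean, sd, False)


def differential_expression(
    matrix: ReadCountMatrix,
    cond_treat: str,
    cond_ref: str,
    alpha: float = 0.05,
    *,
    log_scale: bool = True,
    welch: bool = False,
    bh_correction: bool = False,
) -> list[DifferentialExpressionRecord]:
    """Per-gene two-sided two-sample t-test between two conditions.

    The test runs on log2(CPM + 1) by default (variance stabilization for
    counts; ``log_scale=False`` tests the CPM scale directly) and pools
    variances (Student's test; ``welch=True`` switches to Welch).  The
    p-value is undefined (``None``) when both groups are constant.  With
    ``bh_correction`` the significance flag applies Benjamini-Hochberg to the
    defined p-values; otherwise raw p-values are compared with ``alpha``.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    treat_samples = matrix.samples_for(cond_treat)
    ref_samples = matrix.samples_for(cond_ref)
    if len(treat_samples) < 2 or len(ref_samples) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition for the t-test; "
            f"{cond_treat!r} has {len(treat_samples)}, {cond_ref!r} has {len(ref_samples)}"
        )
    normalized = normalize_counts(matrix)
    expr = np.log2(normalized + 1.0) if log_scale else normalized
    treat = expr[treat_samples].to_numpy(dtype=float)
    ref = expr[ref_samples].to_numpy(dtype=float)

    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, pvals = stats.ttest_ind(treat, ref, axis=1, equal_var=not welch)
    both_constant = (np.ptp(treat, axis=1) == 0) & (np.ptp(ref, axis=1) == 0)

    records: list[DifferentialExpressionRecord] = []
    for i, gene in enumerate(matrix.counts.index):
        rec = expression_ratio(gene, matrix, cond_treat, cond_ref, normalized=normalized)
        p = None if both_constant[i] or math.isnan(pvals[i]) else float(pvals[i])
        rec.p_value = p
        records.append(rec)

    if bh_correction:
        defined = [r for r in records if r.p_value is not None]
        if defined:
            _, corrected, _, _ = multipletests(
                [r.p_value for r in defined], method="fdr_bh"
            )
            for rec, cp in zip(defined, corrected):
                rec.corrected_p = float(cp)
        for rec in records:
            rec.significant = rec.corrected_p is not None and rec.corrected_p < alpha
    else:
        for rec in records:
            rec.significant = rec.p_value is not None and rec.p_value < alpha
    return records


def de_records_to_frame(records: list[DifferentialExpressionRecord]) -> pd.DataFrame:
    """Tabular view of DE records, with sentinel strings for special ratios."""

    def ratio_repr(rec: DifferentialExpressionRecord) -> str:
        if rec.de_novo:
            return "DE_NOVO"
        if rec.ratio is None:
            return "NA"
        return f"{rec.ratio:.6g}"

    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "p_value": [r.p_value if r.p_value is not None else np.nan for r in records],
            "ratio": [ratio_repr(r) for r in records],
            "ratio_mean": [r.ratio_mean if r.ratio_mean is not None else np.nan for r in records],
            "ratio_sd": [r.ratio_sd if r.ratio_sd is not None else np.nan for r in records],
            "de_novo_flag": [int(r.de_novo) for r in records],
            "significant": [int(r.significant) for r in records],
        }
    )
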