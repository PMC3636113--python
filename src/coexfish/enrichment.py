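"""Hypergeometric over-representation of annotation terms in a gene set.

The statistic is the upper tail of the hypergeometric distribution
(equivalently a one-sided Fisher exact test): with a background of N genes of
which K carry a term, the p-value for observing k or more carriers in a
query of size n is

    p = sum_{i=k..min(n,K)} C(K,i) C(N-K, n-i) / C(N, n).

Terms are reported uncorrected by default (flagged at p < alpha, alpha=0.01);
Benjamini-Hochberg correction is available by flag.  The annotation is a
flat gene -> term table; no term-hierarchy propagation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = ["AnnotationTable", "EnrichmentRecord", "hypergeometric_tail", "enrich"]


@dataclass
class AnnotationTable:
    """Flat gene -> terms mapping over an explicit background gene set."""

    gene_to_terms: dict[str, set[str]]
    background: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.background:
            self.background = set(self.gene_to_terms)
        stray = set(self.gene_to_terms) - self.background
        if stray:
            raise ValueError(f"annotated genes outside the background: {sorted(stray)[:10]}")
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                if not t:
                    raise ValueError(f"empty term for gene {gene!r}")

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]], background: set[str] | None = None
    ) -> "AnnotationTable":
        """Build from (gene, term) rows; duplicate pairs collapse."""
        mapping: dict[str, set[str]] = {}
        for gene, term in pairs:
            mapping.setdefault(gene, set()).add(term)
        return cls(mapping, background or set(mapping))

    def term_to_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out


@dataclass
class EnrichmentRecord:
    term: str
    k: int  # carriers in the query
    K: int  # carriers in the background
    n: int  # query size
    N: int  # background size
    p_value: float
    corrected_p: float | None
    enriched: bool


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K <= N and 0 <= n <= N, got k={k} K={K} n={n} N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k} K={K} n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    annotation: AnnotationTable,
    alpha: float = 0.01,
    *,
    bh_correction: bool = False,
    background: set[str] | None = None,
) -> list[EnrichmentRecord]:
    """Test every term overlapping the query; records sorted by ascending p.

    Query genes outside the background are dropped with a warning; only terms
    with at least one query carrier are reported.  With ``bh_correction`` the
    enriched flag uses BH-adjusted p-values; raw p-values otherwise.
    """
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    bg = set(background) if background is not None else set(annotation.background)
    kept = set(query) & bg
    dropped = set(query) - bg
    if dropped:
        logger.warning("%d query genes outside the background, dropped: %s",
                       len(dropped), sorted(dropped)[:10])
    if not kept:
        raise ValueError("query is empty after restricting to the background")

    N = len(bg)
    n = len(kept)
    records: list[EnrichmentRecord] = []
    for term, genes in sorted(annotation.term_to_genes().items()):
        carriers = genes & bg
        K = len(carriers)
        k = len(carriers & kept)
        if k == 0:
            continue
        p = hypergeometric_tail(k, K, n, N)
        records.append(EnrichmentRecord(term, k, K, n, N, p, None, False))

    records.sort(key=lambda r: (r.p_value, r.term))
    if bh_correction and records:
        _, corrected, _, _ = multipletests([r.p_value for r in records], method="fdr_bh")
        for rec, cp in zip(records, corrected):
            rec.corrected_p = float(cp)
            rec.enriched = cp < alpha
    else:
        for rec in records:
            rec.enriched = rec.p_value < alpha
    return records


def enrichment_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in records],
            "k": [r.k for r in records],
            "K": [r.K for r in records],
            "n": [r.n for r in records],
            "N": [r.N for r in records],
            "p_value": [r.p_value for r in records],
            "corrected_p": [r.corrected_p if r.corrected_p is not None else float("nan") for r in records],
            "enriched": [int(r.enriched) for r in records],
        }
    )
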