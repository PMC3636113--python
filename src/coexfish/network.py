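"""Thresholded Pearson co-expression networks, modules, and bait-prey fishing.

A network is built over a normalized expression compendium (samples x genes)
by keeping every gene pair whose Pearson correlation reaches a cutoff
(default 0.7, inclusive, on the signed correlation).  Two construction modes
are provided:

* guide networks — all pairs within one input gene list are candidates;
* bait-prey networks — candidate pairs span baits and preys, but only edges
  touching at least one bait are retained, so preys enter the network only by
  being "fished" through a bait.

Modules are the connected components of the resulting graph; a module can be
split into sub-modules by removing connector genes (articulation points).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionCompendium",
    "pearson",
    "correlation_matrix",
    "build_guide_network",
    "build_bait_prey_network",
    "find_modules",
    "articulation_candidates",
    "split_module_at_connectors",
    "network_summary",
]

DEFAULT_THRESHOLD = 0.7


@dataclass
class ExpressionCompendium:
    """Normalized real-valued expression over many samples.

    ``values`` is a samples x genes table of finite reals; correlations need
    at least three samples.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        arr = self.values.to_numpy()
        if arr.size and not np.all(np.isfinite(arr)):
            bad = int(np.count_nonzero(~np.isfinite(arr)))
            raise ValueError(f"compendium contains {bad} non-finite values")
        self.values = self.values.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def pearson(x, y) -> float:
    """Product-moment correlation of two equal-length vectors.

    Returns NaN (an undefined correlation, not an error) when either vector
    has zero variance, so callers building networks can drop constant genes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    if x.size < 3:
        raise ValueError(f"need >= 3 observations for a correlation, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _select_genes(compendium: ExpressionCompendium, genes: list[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in compendium.values.columns]
    if missing:
        raise KeyError(f"genes absent from the compendium: {missing}")
    return compendium.values[list(genes)]


def correlation_matrix(compendium: ExpressionCompendium, genes: list[str]) -> pd.DataFrame:
    """Symmetric gene x gene Pearson matrix; NaN rows/columns mark constant genes."""
    if compendium.n_samples < 3:
        raise ValueError(
            f"need >= 3 compendium samples for correlations, got {compendium.n_samples}"
        )
    sub = _select_genes(compendium, genes).to_numpy()
    constant = np.ptp(sub, axis=0) == 0
    if constant.any():
        flagged = [g for g, c in zip(genes, constant) if c]
        logger.warning("constant genes have undefined correlations: %s", flagged)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(corr, index=list(genes), columns=list(genes))


def _dedupe_present(
    compendium: ExpressionCompendium, genes: list[str], label: str
) -> list[str]:
    seen: dict[str, None] = {}
    for g in genes:
        seen.setdefault(g, None)
    present = [g for g in seen if g in compendium.values.columns]
    absent = [g for g in seen if g not in compendium.values.columns]
    if absent:
        logger.warning("%d %s genes absent from compendium, dropped: %s", len(absent), label, absent)
    return present


def _usable_genes(compendium: ExpressionCompendium, genes: list[str], label: str) -> list[str]:
    sub = compendium.values[genes].to_numpy()
    constant = np.ptp(sub, axis=0) == 0
    if constant.any():
        flagged = [g for g, c in zip(genes, constant) if c]
        logger.warning("%d constant %s genes dropped: %s", len(flagged), label, flagged)
    return [g for g, c in zip(genes, constant) if not c]


def _new_network(threshold: float, absolute: bool) -> nx.Graph:
    graph = nx.Graph()
    graph.graph["threshold"] = float(threshold)
    graph.graph["absolute"] = bool(absolute)
    return graph


def build_guide_network(
    compendium: ExpressionCompendium,
    guides: list[str],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    absolute: bool = False,
) -> nx.Graph:
    """Co-expression network over a guide-gene list.

    An edge joins two guides when their correlation reaches the cutoff
    (``r >= threshold``, or ``|r| >= threshold`` with ``absolute``).  Guides
    left without any retained edge are not nodes of the network, so the node
    set can be much smaller than the input list.
    """
    if not guides:
        raise ValueError("guide list is empty")
    if compendium.n_samples < 3:
        raise ValueError(
            f"need >= 3 compendium samples, got {compendium.n_samples}"
        )
    kept = _usable_genes(compendium, _dedupe_present(compendium, guides, "guide"), "guide")
    graph = _new_network(threshold, absolute)
    if len(kept) < 2:
        return graph
    corr = correlation_matrix(compendium, kept).to_numpy()
    score = np.abs(corr) if absolute else corr
    for i in range(len(kept)):
        for j in range(i + 1, len(kept)):
            if score[i, j] >= threshold:
                a, b = sorted((kept[i], kept[j]))
                graph.add_edge(a, b, r=float(corr[i, j]))
    for node in graph.nodes:
        graph.nodes[node]["role"] = "guide"
    return graph


def build_bait_prey_network(
    compendium: ExpressionCompendium,
    baits: list[str],
    preys: list[str],
    threshold: float = DEFAULT_THRESHOLD,
    *,
    absolute: bool = False,
) -> nx.Graph:
    """Fishing-style network: edges must touch at least one bait.

    Candidate edges are all pairs over baits and preys with correlation at or
    above the cutoff; prey-prey candidates are discarded, so every retained
    prey ("fished" gene) is connected to some bait.  Ids listed as both bait
    and prey are treated as baits.
    """
    if not baits:
        raise ValueError("bait list is empty")
    bait_set = dict.fromkeys(baits)
    overlap = [p for p in preys if p in bait_set]
    if overlap:
        logger.warning("%d ids in both bait and prey lists, kept as baits: %s", len(overlap), overlap)
    prey_list = [p for p in dict.fromkeys(preys) if p not in bait_set]

    kept_baits = _usable_genes(
        compendium, _dedupe_present(compendium, list(bait_set), "bait"), "bait"
    )
    kept_preys = _usable_genes(
        compendium, _dedupe_present(compendium, prey_list, "prey"), "prey"
    )
    graph = _new_network(threshold, absolute)
    genes = kept_baits + kept_preys
    roles = {g: "bait" for g in kept_baits}
    roles.update({g: "prey" for g in kept_preys})
    if len(genes) < 2:
        return graph
    corr = correlation_matrix(compendium, genes).to_numpy()
    score = np.abs(corr) if absolute else corr
    n_bait = len(kept_baits)
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            if i >= n_bait and j >= n_bait:
                continue  # prey-prey edges are excluded
            if score[i, j] >= threshold:
                a, b = sorted((genes[i], genes[j]))
                graph.add_edge(a, b, r=float(corr[i, j]))
    for node in graph.nodes:
        graph.nodes[node]["role"] = roles[node]
    return graph


def fished_preys(graph: nx.Graph) -> list[str]:
    """Prey nodes retained in a bait-prey network, sorted."""
    return sorted(n for n, d in graph.nodes(data=True) if d.get("role") == "prey")


def find_modules(graph: nx.Graph) -> list[set[str]]:
    """Connected components, largest first; ties broken by smallest member id."""
    components = [set(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    return components


def articulation_candidates(graph: nx.Graph, module: set[str]) -> list[str]:
    """Articulation points of a module's induced subgraph — candidate connectors."""
    sub = graph.subgraph(module)
    return sorted(nx.articulation_points(sub))


def split_module_at_connectors(
    graph: nx.Graph, module: set[str], connectors: set[str]
) -> tuple[list[set[str]], list[str]]:
    """Sub-modules obtained by deleting connector genes from a module.

    Returns the connected components of the induced subgraph minus the
    connectors (ordered as in :func:`find_modules`) together with the sorted
    connector list.
    """
    stray = set(connectors) - set(module)
    if stray:
        raise ValueError(f"connectors not in module: {sorted(stray)}")
    remaining = set(module) - set(connectors)
    sub = graph.subgraph(remaining)
    parts = [set(c) for c in nx.connected_components(sub)]
    parts.sort(key=lambda c: (-len(c), min(c)))
    return parts, sorted(connectors)


def network_summary(graph: nx.Graph) -> dict:
    """Node/edge/role/degree/module bookkeeping for a network."""
    roles: dict[str, int] = {}
    for _, data in graph.nodes(data=True):
        role = data.get("role", "guide")
        roles[role] = roles.get(role, 0) + 1
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "nodes_by_role": dict(sorted(roles.items())),
        "degree": {n: int(d) for n, d in sorted(graph.degree)},
        "n_modules": len(find_modules(graph)),
    }
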