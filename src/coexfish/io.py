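"""Plain-text readers and writers for every pipeline format.

Inputs are tab-separated text: a genes x samples count table plus a
two-column sample -> condition map, a samples x genes compendium, one-id-per-
line gene lists ('#' comments allowed) and a two-column gene/term annotation.
Malformed cells are reported with their line number.  Network exports are
SIF ("geneA co geneB"), GraphML (node attributes ``role`` and
``direction_tag``, edge attribute ``r`` to six decimals) and an edge-list
TSV; all three round-trip node and edge sets and use a fixed ordering so
identical networks produce byte-identical files.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import AnnotationTable
from .expression import ReadCountMatrix
from .network import ExpressionCompendium

__all__ = [
    "read_counts",
    "write_counts",
    "read_compendium",
    "write_compendium",
    "read_gene_list",
    "write_gene_list",
    "read_annotation",
    "write_annotation",
    "export_network",
    "write_sif",
    "read_sif",
    "write_edge_tsv",
    "read_edge_tsv",
    "write_graphml",
    "read_graphml",
]

NETWORK_FORMATS = ("sif", "graphml", "tsv")
SIF_INTERACTION = "co"


def _read_table_rows(path: Path) -> list[list[str]]:
    with open(path, newline="") as handle:
        return [row for row in csv.reader(handle, delimiter="\t")]


def read_counts(counts_path, sample_map_path) -> ReadCountMatrix:
    """Load a count TSV (first column gene id) plus its sample/condition map."""
    counts_path = Path(counts_path)
    rows = _read_table_rows(counts_path)
    if not rows:
        raise ValueError(f"{counts_path}: empty count table")
    header = rows[0]
    samples = header[1:]
    n_cols = len(header)
    gene_ids: list[str] = []
    seen: dict[str, int] = {}
    data: list[list[int]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ValueError(
                f"{counts_path}:{lineno}: ragged row ({len(row)} fields, expected {n_cols})"
            )
        gene = row[0]
        if gene in seen:
            raise ValueError(
                f"{counts_path}:{lineno}: duplicate gene id {gene!r} (first seen line {seen[gene]})"
            )
        seen[gene] = lineno
        values: list[int] = []
        for sample, cell in zip(samples, row[1:]):
            try:
                value = int(cell)
            except ValueError:
                raise ValueError(
                    f"{counts_path}:{lineno}: non-integer count {cell!r} in sample {sample!r}"
                ) from None
            values.append(value)
        gene_ids.append(gene)
        data.append(values)

    conditions = read_sample_map(sample_map_path)
    counts = pd.DataFrame(data, index=gene_ids, columns=samples, dtype=np.int64)
    return ReadCountMatrix(counts=counts, conditions=conditions)


def read_sample_map(path) -> pd.Series:
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, row in enumerate(_read_table_rows(path), start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if row[0].startswith("#"):
            continue
        if len(row) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'sample<TAB>condition', got {row!r}")
        sample, condition = row
        if sample in mapping:
            raise ValueError(f"{path}:{lineno}: duplicate sample id {sample!r}")
        mapping[sample] = condition
    return pd.Series(mapping)


def write_counts(matrix: ReadCountMatrix, counts_path, sample_map_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    with open(sample_map_path, "w") as handle:
        for sample in matrix.sample_ids:
            handle.write(f"{sample}\t{matrix.conditions[sample]}\n")


def read_compendium(path) -> ExpressionCompendium:
    """Load a samples x genes TSV (first column sample id); rejects non-finite cells."""
    path = Path(path)
    rows = _read_table_rows(path)
    if not rows:
        raise ValueError(f"{path}: empty compendium")
    header = rows[0]
    genes = header[1:]
    n_cols = len(header)
    sample_ids: list[str] = []
    data: list[list[float]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ValueError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, expected {n_cols})"
            )
        sample_ids.append(row[0])
        values: list[float] = []
        for gene, cell in zip(genes, row[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value {cell!r} for gene {gene!r}"
                ) from None
            if not np.isfinite(value):
                raise ValueError(
                    f"{path}:{lineno}: non-finite value {cell!r} for gene {gene!r}"
                )
            values.append(value)
        data.append(values)
    frame = pd.DataFrame(data, index=sample_ids, columns=genes, dtype=float)
    return ExpressionCompendium(values=frame)


def write_compendium(compendium: ExpressionCompendium, path) -> None:
    compendium.values.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_gene_list(path) -> list[str]:
    """One id per line; '#' starts a comment; order preserved, duplicates collapsed."""
    out: dict[str, None] = {}
    for line in Path(path).read_text().splitlines():
        text = line.split("#", 1)[0].strip()
        if text:
            out.setdefault(text, None)
    return list(out)


def write_gene_list(genes: list[str], path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_annotation(path, background: set[str] | None = None) -> AnnotationTable:
    """Two-column gene<TAB>term TSV; duplicate pairs collapse."""
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, row in enumerate(_read_table_rows(path), start=1):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if row[0].startswith("#"):
            continue
        if len(row) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'gene<TAB>term', got {row!r}")
        gene, term = row
        if not term:
            raise ValueError(f"{path}:{lineno}: empty term for gene {gene!r}")
        pairs.append((gene, term))
    return AnnotationTable.from_pairs(pairs, background=background)


def write_annotation(annotation: AnnotationTable, path) -> None:
    with open(path, "w") as handle:
        for gene in sorted(annotation.gene_to_terms):
            for term in sorted(annotation.gene_to_terms[gene]):
                handle.write(f"{gene}\t{term}\n")


def _sorted_edges(graph: nx.Graph) -> list[tuple[str, str, float]]:
    edges = []
    for a, b, data in graph.edges(data=True):
        lo, hi = sorted((a, b))
        edges.append((lo, hi, float(data.get("r", float("nan")))))
    return sorted(edges, key=lambda e: (e[0], e[1]))


def write_sif(graph: nx.Graph, path) -> None:
    """Simple interaction format; isolated nodes appear as bare lines."""
    lines = [f"{a}\t{SIF_INTERACTION}\t{b}" for a, b, _ in _sorted_edges(graph)]
    lines.extend(str(n) for n in sorted(graph.nodes) if graph.degree(n) == 0)
    Path(path).write_text("".join(f"{line}\n" for line in lines))


def read_sif(path) -> nx.Graph:
    graph = nx.Graph()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            graph.add_node(fields[0])
        elif len(fields) == 3:
            graph.add_edge(fields[0], fields[2])
        else:
            raise ValueError(f"{path}:{lineno}: malformed SIF line {line!r}")
    return graph


def write_edge_tsv(graph: nx.Graph, path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_a\tgene_b\tr\n")
        for a, b, r in _sorted_edges(graph):
            handle.write(f"{a}\t{b}\t{r:.6f}\n")


def read_edge_tsv(path) -> nx.Graph:
    path = Path(path)
    graph = nx.Graph()
    rows = _read_table_rows(path)
    if not rows or rows[0][:3] != ["gene_a", "gene_b", "r"]:
        raise ValueError(f"{path}: missing edge-list header")
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 fields, got {row!r}")
        graph.add_edge(row[0], row[1], r=float(row[2]))
    return graph


def _normalized_copy(graph: nx.Graph) -> nx.Graph:
    """Copy with sorted node/edge insertion so writers emit a fixed order."""
    out = nx.Graph()
    out.graph.update(graph.graph)
    for node in sorted(graph.nodes):
        data = graph.nodes[node]
        out.add_node(
            node,
            role=str(data.get("role", "guide")),
            direction_tag=str(data.get("direction_tag", "unchanged")),
        )
    for a, b, r in _sorted_edges(graph):
        out.add_edge(a, b, r=round(r, 6))
    return out


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(_normalized_copy(graph), path, infer_numeric_types=False)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def export_network(graph: nx.Graph, path, format: str) -> None:
    """Write a network as SIF, GraphML or edge-list TSV."""
    fmt = format.lower()
    if fmt == "sif":
        write_sif(graph, path)
    elif fmt == "graphml":
        write_graphml(graph, path)
    elif fmt == "tsv":
        write_edge_tsv(graph, path)
    else:
        raise ValueError(f"unknown network format {format!r}; use one of {NETWORK_FORMATS}")
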