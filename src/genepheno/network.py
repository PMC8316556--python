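"""Phenotype-sharing gene interaction network and betweenness ranking.

Two genes are linked when they share a standardized phenotype with which
both have an association at or above a global NPMI threshold (by default
the arithmetic mean NPMI over all retained associations). Parallel links
from several shared phenotypes are compressed into one undirected edge
whose weight is the number of shared qualifying phenotypes. Genes are
ranked by betweenness centrality

    C_B(v) = sum over pairs s != v != t of sigma_st(v) / sigma_st

where sigma_st counts shortest s-t paths and sigma_st(v) those through v;
each unordered pair counts once (raw sum, no normalization). In weighted
mode edge weight is an affinity, so path length uses distance = 1/weight
(more shared phenotypes = closer); a flag switches to distance = weight.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Sequence

import networkx as nx

from .association import AssociationRecord

logger = logging.getLogger(__name__)

__all__ = ["global_average_npmi", "build_graph", "betweenness_centrality",
           "top_fraction", "subset_by_phenotype_keyword", "write_edge_list",
           "write_centrality"]


def global_average_npmi(
    records: Sequence[AssociationRecord], positive_only: bool = False
) -> float:
    """Arithmetic mean NPMI over retained records.

    With ``positive_only`` the mean is over records with NPMI > 0 only.
    Empty input is fatal.
    """
    values = [r.npmi for r in records if math.isfinite(r.npmi)
              and (not positive_only or r.npmi > 0)]
    if not values:
        raise ValueError("no records to average")
    return sum(values) / len(values)


def build_graph(
    records: Sequence[AssociationRecord],
    node_genes: Iterable[str],
    threshold: float,
    risk_classes: dict[str, str] | None = None,
) -> nx.Graph:
    """Link genes that share a phenotype with NPMI >= threshold for both.

    Nodes are restricted to *node_genes* (e.g. the SFARI-class genes); every
    node gene appears in the graph even if isolated. Edge weight = number of
    shared qualifying phenotypes.
    """
    nodes = set(node_genes)
    graph = nx.Graph()
    for g in sorted(nodes):
        graph.add_node(g, risk_class=(risk_classes or {}).get(g, "NA"))
    by_phen: dict[str, set[str]] = {}
    for r in records:
        if r.gene in nodes and r.npmi >= threshold:
            by_phen.setdefault(r.phenotype.concept_id, set()).add(r.gene)
    for _, members in sorted(by_phen.items()):
        ordered = sorted(members)
        for i, g1 in enumerate(ordered):
            for g2 in ordered[i + 1:]:
                if graph.has_edge(g1, g2):
                    graph[g1][g2]["weight"] += 1
                else:
                    graph.add_edge(g1, g2, weight=1)
    return graph


def betweenness_centrality(
    graph: nx.Graph, weighted: bool = False, affinity_weights: bool = True
) -> dict[str, float]:
    """Raw (unnormalized) betweenness scores per gene.

    In weighted mode the shared-phenotype count is an affinity, so the path
    length of an edge is 1/weight; set ``affinity_weights=False`` to use the
    weight itself as a distance.
    """
    if weighted:
        for _, _, data in graph.edges(data=True):
            w = data["weight"]
            data["length"] = (1.0 / w) if affinity_weights else float(w)
        scores = nx.betweenness_centrality(graph, normalized=False, weight="length")
    else:
        scores = nx.betweenness_centrality(graph, normalized=False)
    return {g: float(s) for g, s in scores.items()}


def top_fraction(
    scores: dict[str, float], fraction: float = 0.10
) -> list[str]:
    """The ceil(fraction * n) genes with the highest scores.

    Descending score, ties broken by symbol order (ties at the cut are thus
    resolved deterministically and visibly by name).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_select = math.ceil(fraction * len(scores))
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:n_select]]


def subset_by_phenotype_keyword(
    records: Sequence[AssociationRecord],
    keywords: Sequence[str],
    threshold: float,
    node_genes: Iterable[str] | None = None,
) -> tuple[list[AssociationRecord], nx.Graph]:
    """Keyword-filtered association subset and its induced sharing graph.

    Keywords match case-insensitively against standardized preferred names.
    The induced graph links genes through the matching phenotypes only.
    """
    if not keywords:
        raise ValueError("at least one keyword required")
    lowered = [k.lower() for k in keywords]
    subset = [r for r in records
              if any(k in r.phenotype.preferred_name.lower() for k in lowered)]
    if not subset:
        logger.warning("no phenotype matched keywords %s", list(keywords))
    genes = set(node_genes) if node_genes is not None else {r.gene for r in subset}
    graph = build_graph(subset, genes, threshold)
    graph.remove_nodes_from([g for g in list(graph) if graph.degree(g) == 0])
    return subset, graph


def write_edge_list(graph: nx.Graph, path) -> None:
    from pathlib import Path
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tweight\n")
        for g1, g2, data in sorted(graph.edges(data=True)):
            fh.write(f"{g1}\t{g2}\t{data['weight']}\n")


def write_centrality(scores: dict[str, float], path,
                     risk_classes: dict[str, str] | None = None) -> None:
    from pathlib import Path
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene\tbetweenness\trisk_class\n")
        for g, s in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])):
            fh.write(f"{g}\t{s:.6f}\t{(risk_classes or {}).get(g, 'NA')}\n")
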