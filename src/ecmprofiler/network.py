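"""Interactome merging, ortholog mapping and hit-subnetwork topology.

A merged human interactome is built as the undirected union of several edge
lists (e.g. a genome-scale PPI network, a dedicated ECM interaction database
and a curated adhesion-complex list), keeping per-edge source provenance.
Mouse gene symbols are converted to human orthologs before mapping hits. The
subnetwork induced on a hit list is measured with the standard topology
metrics: node degree k, local clustering coefficient
C(v) = 2 e(v) / (k (k - 1)) (0 when k < 2, with e(v) the number of edges among
v's neighbors), and network density rho = 2 E / (N (N - 1)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = ["merge_interactomes", "map_orthologs", "NetworkReport", "induce_and_measure"]

logger = logging.getLogger(__name__)


def merge_interactomes(edge_lists: Sequence[pd.DataFrame]) -> nx.Graph:
    """Merge edge lists (columns a, b, source) into one undirected simple graph.

    A-B and B-A collapse onto one edge whose ``sources`` attribute accumulates
    every list naming it; self-loops are dropped and counted in the graph
    attribute ``self_loops_dropped``.
    """
    if not edge_lists:
        raise ValueError("need at least one edge list")
    G = nx.Graph(self_loops_dropped=0)
    for df in edge_lists:
        for row in df.itertuples(index=False):
            if row.a == row.b:
                G.graph["self_loops_dropped"] += 1
                logger.warning("dropping self-loop %s-%s (source %s)", row.a, row.b, row.source)
                continue
            if G.has_edge(row.a, row.b):
                G.edges[row.a, row.b]["sources"].add(row.source)
            else:
                G.add_edge(row.a, row.b, sources={row.source})
    return G


def map_orthologs(
    symbols: Iterable[str], ortholog_map: Mapping[str, str]
) -> tuple[frozenset[str], list[str]]:
    """Convert mouse symbols to human orthologs.

    Returns the deduplicated human symbol set and the list of mouse symbols
    without a mapping (excluded, logged).
    """
    mapped: set[str] = set()
    unmapped: list[str] = []
    for s in symbols:
        if s in ortholog_map:
            mapped.add(ortholog_map[s])
        else:
            unmapped.append(s)
    if unmapped:
        logger.warning("%d symbol(s) without ortholog mapping: %s", len(unmapped), unmapped)
    return frozenset(mapped), unmapped


@dataclass
class NetworkReport:
    """Induced hit subnetwork with per-node and global topology metrics."""

    graph: nx.Graph
    degree: dict[str, int]
    clustering: dict[str, float]
    density: float
    n_nodes: int  # nodes entering the density denominator
    n_edges: int
    hubs: list[str]  # hit proteins by descending degree, ties by symbol
    hits_not_in_network: list[str]
    include_isolates: bool = field(default=False)


def induce_and_measure(
    interactome: nx.Graph,
    hits: Iterable[str],
    include_isolates: bool = False,
) -> NetworkReport:
    """Induce the subnetwork on ``hits`` and compute its topology metrics.

    Degree and clustering coefficient are computed within the induced
    subnetwork. Density defaults to the connected-node convention (isolated
    hits excluded from N, matching network figures that hide disconnected
    nodes); ``include_isolates=True`` switches to all mapped hit nodes.
    """
    hits = list(dict.fromkeys(hits))
    if not hits:
        raise ValueError("empty hit set")
    present = [h for h in hits if h in interactome]
    missing = [h for h in hits if h not in interactome]
    if missing:
        logger.warning("%d hit(s) absent from interactome: %s", len(missing), missing)
    sub = interactome.subgraph(present).copy()

    degree = {v: int(d) for v, d in sub.degree()}
    clustering = {v: float(c) for v, c in nx.clustering(sub).items()}
    nodes = list(sub.nodes) if include_isolates else [v for v, d in degree.items() if d > 0]
    N, E = len(nodes), sub.number_of_edges()
    density = 2.0 * E / (N * (N - 1)) if N >= 2 else 0.0
    hubs = sorted(degree, key=lambda v: (-degree[v], v))
    return NetworkReport(sub, degree, clustering, density, N, E, hubs, missing, include_isolates)


def export_node_table(report: NetworkReport, path) -> None:
    """Write node metrics as TSV (symbol, degree, clustering coefficient)."""
    rows = [
        {"gene_symbol": v, "degree": report.degree[v], "clustering_coefficient": report.clustering[v]}
        for v in sorted(report.graph.nodes)
    ]
    pd.DataFrame(rows, columns=["gene_symbol", "degree", "clustering_coefficient"]).to_csv(
        path, sep="\t", index=False
    )


def export_edge_list(graph: nx.Graph, path) -> None:
    """Write edges as TSV (a, b, source tags joined by ';')."""
    rows = [
        {"a": a, "b": b, "source": ";".join(sorted(data.get("sources", set())))}
        for a, b, data in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["a", "b", "source"]).to_csv(path, sep="\t", index=False)
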