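"""Bipartite compensatory network construction and core truncation.

The full network joins compensatory miRs to their rescued targets (directed
miR -> gene repression edges; optional auxiliary gene-gene edges are
treated as bidirectional). The core is extracted PathLinker-style: a
virtual super-source is attached to every source miR, loopless paths to
gene nodes are enumerated in nondecreasing length (uniform edge weights,
ties broken lexicographically by the node-id sequence), and the union of
nodes and edges on the first ``max_paths`` paths is kept. Coverage is the
fraction of rescued genes the core retains.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .compensatory import CompensatoryCall
from .interactions import InteractionTable


def build_network(
    call: CompensatoryCall,
    interactions: InteractionTable,
    gene_gene_edges: set[tuple[str, str]] | None = None,
) -> nx.DiGraph:
    """Directed graph of compensatory miRs and rescued genes.

    Nodes are the compensatory miRs (``kind="miR"``, with ``target_count``)
    and all rescued genes (``kind="gene"``, ``rescued=True``); edges are
    the retained interactions between included nodes. Auxiliary gene-gene
    edges, when supplied, are added in both directions between genes
    already in the network.
    """
    g = nx.DiGraph()
    for m, targets in sorted(call.comp_mirs.items()):
        g.add_node(m, kind="miR", target_count=len(targets))
    for gene in sorted(call.rescued_genes):
        g.add_node(gene, kind="gene", rescued=True)
    for m, gene in sorted(interactions.edges()):
        if m in call.comp_mirs and gene in call.rescued_genes:
            g.add_edge(m, gene, edge_type="miR-gene")
    for m in call.comp_mirs:
        # restrict attribute to planted definition: out-degree into rescued
        g.nodes[m]["target_count"] = sum(
            1 for _, v in g.out_edges(m) if g.nodes[v]["kind"] == "gene"
        )
    if gene_gene_edges:
        for a, b in sorted(gene_gene_edges):
            if a in g and b in g and g.nodes[a]["kind"] == g.nodes[b]["kind"] == "gene":
                g.add_edge(a, b, edge_type="gene-gene")
                g.add_edge(b, a, edge_type="gene-gene")
    return g


@dataclass
class CoreNetwork:
    """Subnetwork spanned by the first k source-to-gene shortest paths."""

    graph: nx.DiGraph
    paths_used: int
    coverage: float  # fraction of rescued genes retained

    def validate(self, parent: nx.DiGraph) -> None:
        if not set(self.graph.nodes) <= set(parent.nodes):
            raise ValueError("core nodes not a subset of the parent network")
        if not set(self.graph.edges) <= set(parent.edges):
            raise ValueError("core edges not a subset of the parent network")
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage outside [0, 1]")


def k_shortest_source_gene_paths(
    net: nx.DiGraph, sources: set[str], max_paths: int
) -> list[list[str]]:
    """First ``max_paths`` loopless source-to-gene paths in (length, lex) order.

    A virtual super-source feeds every source node; simple paths are
    enumerated best-first so that paths emerge in nondecreasing hop count
    with exact lexicographic tie-breaking on the node-id sequence. Every
    simple path whose terminal node is a gene counts as one path (a path
    may continue through a gene via auxiliary edges and yield further,
    longer paths).
    """
    missing = sources - set(net.nodes)
    if missing:
        raise ValueError(f"sources absent from network: {sorted(missing)}")
    paths: list[list[str]] = []
    # heap entries: (length, node sequence); tuple comparison gives the
    # required (length, lexicographic) total order
    heap: list[tuple[int, tuple[str, ...]]] = [(0, (s,)) for s in sorted(sources)]
    heapq.heapify(heap)
    while heap and len(paths) < max_paths:
        length, path = heapq.heappop(heap)
        node = path[-1]
        if net.nodes[node].get("kind") == "gene":
            paths.append(list(path))
        for nxt in net.successors(node):
            if nxt not in path:
                heapq.heappush(heap, (length + 1, path + (nxt,)))
    return paths


def truncate_core(
    net: nx.DiGraph, sources: set[str], max_paths: int = 1000
) -> CoreNetwork:
    """Keep the union of the first ``max_paths`` shortest source-to-gene paths."""
    if not sources:
        raise ValueError("empty source set")
    paths = k_shortest_source_gene_paths(net, sources, max_paths)
    core = nx.DiGraph()
    for p in paths:
        for n in p:
            core.add_node(n, **net.nodes[n])
        for a, b in zip(p, p[1:]):
            core.add_edge(a, b, **net.edges[a, b])
    rescued_all = {n for n, d in net.nodes(data=True) if d.get("rescued")}
    rescued_core = {n for n in core.nodes if n in rescued_all}
    coverage = len(rescued_core) / len(rescued_all) if rescued_all else 0.0
    out = CoreNetwork(graph=core, paths_used=len(paths), coverage=coverage)
    out.validate(net)
    return out


def write_graphml(net: nx.DiGraph, path: str) -> None:
    nx.write_graphml(net, path)


def edge_list_frame(net: nx.DiGraph) -> pd.DataFrame:
    """Cytoscape-ready edge list: source, target, edge_type."""
    rows = [
        {"source": a, "target": b, "edge_type": d.get("edge_type", "miR-gene")}
        for a, b, d in sorted(net.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "edge_type"])


def node_attr_frame(net: nx.DiGraph) -> pd.DataFrame:
    """Node attribute table: node, type, target_count, rescued."""
    rows = [
        {
            "node": n,
            "type": d.get("kind", "gene"),
            "target_count": d.get("target_count", 0),
            "rescued": bool(d.get("rescued", False)),
        }
        for n, d in sorted(net.nodes(data=True))
    ]
    return pd.DataFrame(rows, columns=["node", "type", "target_count", "rescued"])
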