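"""Weighted co-occurrence graphs, Louvain modules and topology metrics.

Validated edges become a simple weighted undirected graph (weight = the
aveF correlation for family networks, the profile correlation for
species networks); nodes exist only through edges, so isolated families
never appear.  Modules come from seeded Louvain modularity maximization
at a configurable resolution (default 1).  A Newman-Girvan weighted
modularity above about 0.4 is conventionally read as evidence of
modular structure.

Path metrics (average shortest path, diameter) use unweighted hop
counts on the largest connected component; the clustering coefficient
is the unweighted average local coefficient over all nodes, with nodes
of degree < 2 contributing 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import pandas as pd

from .cooccurrence import EdgeRecord, SpeciesEdge


@dataclass
class Partition:
    """A module assignment for every node of one graph."""

    assignment: dict
    resolution: float
    seed: int

    def modules(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, set()).add(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    modularity_Q: float
    n_modules: int
    avg_clustering: float
    avg_path_length: Optional[float]
    diameter: Optional[int]


def build_graph(edges: Iterable[Union[EdgeRecord, SpeciesEdge]]) -> nx.Graph:
    """Simple weighted graph over edge endpoints; no isolated nodes.

    :class:`EdgeRecord` inputs must be validated ones (unvalidated
    records are rejected rather than silently dropped, so callers filter
    explicitly); the weight is rho_ave for family edges and rho for
    species edges.
    """
    g = nx.Graph()
    for e in edges:
        if isinstance(e, EdgeRecord):
            if not e.validated:
                raise ValueError(
                    f"edge {e.a}-{e.b} is not validated; filter before building"
                )
            a, b, w, strength = e.a, e.b, e.rho_ave, e.strength
        else:
            a, b, w, strength = e.a, e.b, e.rho, None
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if g.has_edge(a, b):
            if g[a][b]["weight"] != w:
                raise ValueError(
                    f"duplicate edge {a}-{b} with conflicting weights "
                    f"{g[a][b]['weight']} vs {w}"
                )
            continue
        attrs = {"weight": float(w)}
        if strength is not None:
            attrs["strength"] = strength
        g.add_edge(a, b, **attrs)
    return g


def modularity_Q(graph: nx.Graph, partition: Union[Partition, Mapping]) -> float:
    """Newman-Girvan weighted modularity of a partition.

    Q = sum over modules c of [ W_c/W - (S_c/2W)^2 ] where W is the total
    edge weight, W_c the intra-module weight and S_c the summed weighted
    degree of c's nodes.
    """
    assignment = partition.assignment if isinstance(partition, Partition) else dict(partition)
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    two_m = sum(d for _, d in graph.degree(weight="weight"))
    if two_m == 0:
        return 0.0
    intra: dict = {}
    deg_sum: dict = {}
    for node, d in graph.degree(weight="weight"):
        c = assignment[node]
        deg_sum[c] = deg_sum.get(c, 0.0) + d
    for u, v, w in graph.edges(data="weight", default=1.0):
        if assignment[u] == assignment[v]:
            c = assignment[u]
            intra[c] = intra.get(c, 0.0) + w
    q = 0.0
    for c, s in deg_sum.items():
        q += 2.0 * intra.get(c, 0.0) / two_m - (s / two_m) ** 2
    return q


def detect_modules(graph: nx.Graph, resolution: float = 1.0, seed: int = 0) -> Partition:
    """Seeded Louvain partition; identical seed gives identical modules."""
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot detect modules in an empty graph")
    comms = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    # stable module ids: biggest module first, ties broken by smallest member
    comms = sorted(comms, key=lambda c: (-len(c), min(map(str, c))))
    assignment = {node: i for i, comm in enumerate(comms) for node in comm}
    return Partition(assignment=assignment, resolution=resolution, seed=seed)


def topology_summary(graph: nx.Graph, partition: Optional[Partition] = None) -> NetworkSummary:
    """Node/edge counts, modularity, clustering and hop-based path metrics."""
    n_nodes = graph.number_of_nodes()
    n_edges = graph.number_of_edges()
    if n_nodes == 0:
        return NetworkSummary(0, 0, 0.0, 0, 0.0, None, None)
    if partition is None:
        q, n_modules = 0.0, 0
    else:
        q = modularity_Q(graph, partition)
        n_modules = len({partition.assignment[n] for n in graph.nodes})
    clustering = nx.clustering(graph)  # unweighted; degree<2 nodes give 0
    avg_clust = sum(clustering.values()) / n_nodes
    largest = max(nx.connected_components(graph), key=len)
    sub = graph.subgraph(largest)
    if sub.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(sub)  # unweighted hops
        diam = nx.diameter(sub)
    else:
        apl, diam = None, None
    return NetworkSummary(
        n_nodes=n_nodes,
        n_edges=n_edges,
        modularity_Q=q,
        n_modules=n_modules,
        avg_clustering=avg_clust,
        avg_path_length=apl,
        diameter=diam,
    )


def module_phylum_composition(
    partition: Partition, taxonomy: Mapping[str, str]
) -> pd.DataFrame:
    """Per-module phylum counts and fractions (species networks).

    ``taxonomy`` maps each node to its phylum and must cover every node.
    """
    missing = sorted(set(partition.assignment) - set(taxonomy))
    if missing:
        raise ValueError(f"taxonomy missing for nodes: {missing}")
    rows = []
    for mod, members in sorted(partition.modules().items()):
        size = len(members)
        counts: dict[str, int] = {}
        for node in members:
            counts[taxonomy[node]] = counts.get(taxonomy[node], 0) + 1
        for phylum in sorted(counts):
            rows.append(
                {
                    "module": mod,
                    "module_size": size,
                    "phylum": phylum,
                    "count": counts[phylum],
                    "fraction": counts[phylum] / size,
                }
            )
    return pd.DataFrame(rows, columns=["module", "module_size", "phylum", "count", "fraction"])


def export_graph(
    graph: nx.Graph,
    partition: Optional[Partition],
    path,
    format: str = "gexf",
) -> None:
    """Write the graph for Gephi; module ids become node attributes."""
    g = graph.copy()
    if partition is not None:
        missing = set(g.nodes) - set(partition.assignment)
        if missing:
            raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
        nx.set_node_attributes(
            g, {n: int(partition.assignment[n]) for n in g.nodes}, "module"
        )
    if format == "gexf":
        nx.write_gexf(g, path)
    elif format == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unsupported export format {format!r}")


def summary_dict(summary: NetworkSummary) -> dict:
    return {
        "n_nodes": summary.n_nodes,
        "n_edges": summary.n_edges,
        "modularity_Q": summary.modularity_Q,
        "n_modules": summary.n_modules,
        "avg_clustering": summary.avg_clustering,
        "avg_path_length": summary.avg_path_length,
        "diameter": summary.diameter,
        "path_metric": "unweighted_hops_largest_component",
        "clustering_metric": "unweighted_mean_local",
    }
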