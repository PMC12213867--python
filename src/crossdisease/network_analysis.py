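"""Directed interaction-network topology, centralities, and hub selection.

Graphs are simple directed graphs (no self-loops, no duplicated ordered
pairs).  Density is computed on the directed graph, E / (N*(N-1)); path
length, diameter and clustering are computed on the undirected projection,
falling back to the largest weakly connected component (with a flag) when
the projection is disconnected.  Degree centralities are normalized by
N - 1, betweenness is computed on the directed graph with the standard
(N-1)(N-2) normalization, and eigenvector centrality is computed on the
undirected projection of the largest component and scaled to unit maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkMetrics",
    "build_graph",
    "topology_metrics",
    "centralities",
    "select_hubs",
    "random_directed_graph",
]

CENTRALITY_METRICS = ("in_degree", "out_degree", "betweenness", "eigenvector")


@dataclass(frozen=True)
class NetworkMetrics:
    """Topology summary of a directed interaction graph."""

    n_nodes: int
    n_edges: int
    density: float
    avg_path_length: Optional[float]
    clustering_coefficient: Optional[float]
    diameter: Optional[int]
    n_components: int
    connected: bool  # undirected projection connected; else path metrics are
    # reported on the largest weak component


def build_graph(edge_rows: Iterable[Sequence]) -> nx.DiGraph:
    """Build a simple directed graph from (source, target[, polarity]) rows.

    Duplicate ordered pairs are collapsed (count logged) and self-loops are
    dropped with a warning.  A third element, if present, is stored as the
    edge's ``polarity`` attribute.
    """
    g = nx.DiGraph()
    n_dup = n_loop = 0
    for row in edge_rows:
        src, dst = str(row[0]), str(row[1])
        if src == dst:
            n_loop += 1
            continue
        if g.has_edge(src, dst):
            n_dup += 1
            continue
        attrs = {}
        if len(row) > 2 and row[2] is not None:
            attrs["polarity"] = str(row[2])
        g.add_edge(src, dst, **attrs)
    if n_loop:
        logger.warning("dropped %d self-loop edge(s)", n_loop)
    if n_dup:
        logger.info("collapsed %d duplicate ordered pair(s)", n_dup)
    return g


def topology_metrics(g: nx.DiGraph) -> NetworkMetrics:
    """Global topology metrics of a directed graph.

    Fewer than 2 nodes yields zero/absent metrics with ``connected=False``.
    """
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 2:
        return NetworkMetrics(
            n_nodes=n, n_edges=e, density=0.0, avg_path_length=None,
            clustering_coefficient=None, diameter=None,
            n_components=n, connected=False,
        )
    density = e / (n * (n - 1))
    und = g.to_undirected()
    n_components = nx.number_connected_components(und)
    connected = n_components == 1
    component = und if connected else und.subgraph(
        max(nx.connected_components(und), key=len)
    )
    if component.number_of_nodes() >= 2:
        avg_path = nx.average_shortest_path_length(component)
        diameter = nx.diameter(component)
    else:
        avg_path, diameter = None, None
    clustering = nx.average_clustering(und)
    return NetworkMetrics(
        n_nodes=n, n_edges=e, density=density, avg_path_length=avg_path,
        clustering_coefficient=clustering, diameter=diameter,
        n_components=n_components, connected=connected,
    )


def centralities(g: nx.DiGraph) -> pd.DataFrame:
    """Per-node centralities: in/out-degree, betweenness, eigenvector.

    In/out-degree are divided by N - 1; betweenness is computed on the
    directed graph with its standard normalization; eigenvector centrality is
    computed on the undirected projection of the largest connected component
    (zero for nodes outside it) and scaled so the maximum is 1.  Rows are
    ordered by node label.
    """
    nodes = sorted(g.nodes())
    if not nodes:
        return pd.DataFrame(columns=["node", *CENTRALITY_METRICS])
    in_deg = nx.in_degree_centrality(g) if len(nodes) > 1 else {nodes[0]: 0.0}
    out_deg = nx.out_degree_centrality(g) if len(nodes) > 1 else {nodes[0]: 0.0}
    btw = nx.betweenness_centrality(g, normalized=True)
    und = g.to_undirected()
    eig = {v: 0.0 for v in nodes}
    if len(nodes) > 1:
        comp = sorted(max(nx.connected_components(und), key=len))
        sub = und.subgraph(comp)
        if sub.number_of_edges() > 0:
            # dense symmetric eigenproblem: components here are small, and
            # the sparse Arnoldi route cannot handle 2-3 node graphs
            a = nx.to_numpy_array(sub, nodelist=comp)
            w, vecs = np.linalg.eigh(a)
            principal = np.abs(vecs[:, int(np.argmax(w))])
            top = principal.max()
            for v, x in zip(comp, principal):
                eig[v] = float(x / top) if top else 0.0
    return pd.DataFrame(
        {
            "node": nodes,
            "in_degree": [in_deg[v] for v in nodes],
            "out_degree": [out_deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
        }
    )


def select_hubs(
    rows: pd.DataFrame, min_metrics: int = 2, quantile: float = 0.8
) -> list[str]:
    """Hub genes: nodes in the top quantile band of >= ``min_metrics`` metrics.

    For each centrality metric a node qualifies when its value is >= the
    empirical ``quantile`` of that metric's values; a hub qualifies in at
    least ``min_metrics`` of the four metrics.  Ties at the threshold all
    qualify, so a degenerate network where every node is equal returns every
    node.  With fewer than five nodes the quintile band is meaningless and
    the rule falls back to the top-1 node per metric (with a warning).
    Returns hub labels sorted lexicographically.
    """
    if rows.empty:
        raise ValueError("centrality table is empty")
    if not 0 < quantile < 1:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    hits = pd.Series(0, index=rows["node"])
    if len(rows) < 5:
        logger.warning(
            "only %d nodes: falling back to top-1 per metric", len(rows)
        )
        for metric in CENTRALITY_METRICS:
            best = rows[metric].max()
            hits[rows.loc[rows[metric] >= best, "node"]] += 1
        min_metrics = min(min_metrics, len(CENTRALITY_METRICS))
    else:
        for metric in CENTRALITY_METRICS:
            cut = rows[metric].quantile(quantile)
            hits[rows.loc[rows[metric] >= cut, "node"]] += 1
    return sorted(hits.index[hits >= min_metrics])


def random_directed_graph(
    n_nodes: int, n_edges: int, seed: int | np.random.Generator = 0
) -> nx.DiGraph:
    """A random simple directed graph with exactly the requested counts.

    Used as a stand-in topology when only a network's size is known (a
    35-node, 206-edge interaction network, say) and for randomized oracle
    tests.  Edges are a uniform sample without replacement from the
    N*(N-1) ordered pairs.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError(f"at most {max_edges} simple directed edges on {n_nodes} nodes")
    labels = [f"N{i:03d}" for i in range(n_nodes)]
    chosen = rng.choice(max_edges, size=n_edges, replace=False)
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for code in chosen:
        i, off = divmod(int(code), n_nodes - 1)
        j = off if off < i else off + 1
        g.add_edge(labels[i], labels[j])
    return g
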