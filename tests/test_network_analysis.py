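import itertools
import math
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from crossdisease.network_analysis import (
    build_graph,
    centralities,
    random_directed_graph,
    select_hubs,
    topology_metrics,
)


# ---------------------------------------------------------------- oracles


def bfs_distances(adj: dict, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def undirected_adjacency(g: nx.DiGraph) -> dict:
    adj = {v: set() for v in g.nodes()}
    for u, v in g.edges():
        adj[u].add(v)
        adj[v].add(u)
    return adj


def brute_force_betweenness(g: nx.DiGraph) -> dict:
    """Directed betweenness by explicit enumeration of all shortest paths
    (path counting over the BFS predecessor structure done longhand)."""
    nodes = list(g.nodes())
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    adj = {v: list(g.successors(v)) for v in nodes}
    for s in nodes:
        dist = bfs_distances(adj, s)
        for t in nodes:
            if t == s or t not in dist:
                continue
            # enumerate every shortest s->t path recursively
            paths = []

            def extend(path):
                u = path[-1]
                if u == t:
                    paths.append(path)
                    return
                for w in adj[u]:
                    if w in dist and dist[w] == dist[u] + 1 and dist[t] >= dist[w]:
                        extend(path + [w])

            extend([s])
            for path in paths:
                for v in path[1:-1]:
                    score[v] += 1 / len(paths)
    norm = (n - 1) * (n - 2) if n > 2 else 1
    return {v: s / norm for v, s in score.items()}


def brute_force_local_clustering(adj: dict, v) -> float:
    nbrs = list(adj[v])
    k = len(nbrs)
    if k < 2:
        return 0.0
    links = sum(
        1 for a, b in itertools.combinations(nbrs, 2) if b in adj[a]
    )
    return 2 * links / (k * (k - 1))


# ------------------------------------------------------------------ tests


class TestBuildGraph:
    def test_empty(self):
        g = build_graph([])
        assert g.number_of_nodes() == 0

    def test_duplicates_collapse_reciprocal_kept(self):
        g = build_graph([("a", "b"), ("a", "b"), ("b", "a")])
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 2

    def test_self_loops_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            g = build_graph([("a", "a"), ("a", "b")])
        assert g.number_of_edges() == 1
        assert "self-loop" in caplog.text

    def test_polarity_attribute_stored(self):
        g = build_graph([("a", "b", "negative")])
        assert g.edges["a", "b"]["polarity"] == "negative"


class TestTopologyMetrics:
    def test_complete_directed_triad(self):
        g = build_graph([(a, b) for a in "abc" for b in "abc" if a != b])
        m = topology_metrics(g)
        assert m.density == 1.0
        assert m.diameter == 1
        assert m.clustering_coefficient == 1.0
        assert m.connected

    def test_directed_three_node_path(self):
        m = topology_metrics(build_graph([("a", "b"), ("b", "c")]))
        assert m.density == pytest.approx(2 / 6)
        assert m.avg_path_length == pytest.approx(4 / 3)
        assert m.diameter == 2
        assert m.clustering_coefficient == 0.0

    def test_density_from_published_network_size(self):
        g = random_directed_graph(35, 206, seed=0)
        m = topology_metrics(g)
        assert m.density == pytest.approx(206 / (35 * 34))
        assert round(m.density, 2) == 0.17

    def test_tiny_graph_has_absent_metrics(self):
        m = topology_metrics(build_graph([]))
        assert m.density == 0.0 and m.avg_path_length is None

    def test_disconnected_reports_largest_component(self):
        g = build_graph([("a", "b"), ("c", "d"), ("d", "e")])
        m = topology_metrics(g)
        assert not m.connected and m.n_components == 2
        assert m.diameter == 2  # on the c-d-e component


class TestCentralities:
    def test_star_center_degrees(self):
        g = build_graph([("c", f"l{i}") for i in range(4)])
        rows = centralities(g).set_index("node")
        assert rows.loc["c", "out_degree"] == 1.0
        assert rows.loc["c", "in_degree"] == 0.0
        assert rows.loc["l0", "in_degree"] == pytest.approx(0.25)

    def test_path_midpoint_betweenness(self):
        rows = centralities(build_graph([("a", "b"), ("b", "c")])).set_index("node")
        assert rows.loc["b", "betweenness"] == pytest.approx(0.5)

    def test_complete_triad_eigenvector_symmetry(self):
        g = build_graph([(a, b) for a in "abc" for b in "abc" if a != b])
        rows = centralities(g)
        assert np.allclose(rows["eigenvector"], 1.0)

    def test_degree_conservation(self):
        g = random_directed_graph(20, 57, seed=3)
        rows = centralities(g)
        n = g.number_of_nodes()
        assert rows["in_degree"].sum() * (n - 1) == pytest.approx(57)
        assert rows["out_degree"].sum() * (n - 1) == pytest.approx(57)

    def test_against_exhaustive_oracles_on_small_graphs(self):
        """Density, path metrics, clustering, degrees and betweenness agree
        with from-scratch BFS / triangle-counting on 100 random graphs with
        at most 12 nodes."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            e = int(rng.integers(0, n * (n - 1) + 1))
            g = random_directed_graph(n, e, seed=rng)
            m = topology_metrics(g)
            assert m.density == pytest.approx(e / (n * (n - 1)))
            adj = undirected_adjacency(g)
            # clustering: mean of local coefficients
            expected_clust = np.mean(
                [brute_force_local_clustering(adj, v) for v in g.nodes()]
            )
            assert m.clustering_coefficient == pytest.approx(expected_clust)
            # path length / diameter on the largest undirected component
            comps = list(nx.connected_components(g.to_undirected()))
            largest = max(comps, key=len)
            if len(largest) >= 2:
                dists = []
                for s in largest:
                    d = bfs_distances({v: adj[v] for v in largest}, s)
                    dists.extend(d[t] for t in largest if t != s)
                assert m.avg_path_length == pytest.approx(np.mean(dists))
                assert m.diameter == max(dists)
            rows = centralities(g).set_index("node")
            for v in g.nodes():
                assert rows.loc[v, "in_degree"] == pytest.approx(
                    g.in_degree(v) / (n - 1)
                )
                assert rows.loc[v, "out_degree"] == pytest.approx(
                    g.out_degree(v) / (n - 1)
                )
            btw = brute_force_betweenness(g)
            for v in g.nodes():
                assert rows.loc[v, "betweenness"] == pytest.approx(
                    btw[v], abs=1e-9
                )

    def test_eigenvector_matches_principal_eigenvector(self):
        g = random_directed_graph(10, 34, seed=5)
        und = g.to_undirected()
        comp = max(nx.connected_components(und), key=len)
        sub = und.subgraph(sorted(comp))
        nodes = sorted(sub.nodes())
        a = nx.to_numpy_array(sub, nodelist=nodes)
        w, v = np.linalg.eigh(a)
        principal = np.abs(v[:, np.argmax(w)])
        principal /= principal.max()
        rows = centralities(g).set_index("node")
        got = rows.loc[nodes, "eigenvector"].to_numpy()
        assert np.allclose(got, principal, atol=1e-6)


class TestSelectHubs:
    def _frame(self, data):
        return pd.DataFrame(data, columns=["node", *["in_degree", "out_degree",
                                                     "betweenness", "eigenvector"]])

    def test_all_equal_returns_every_node(self):
        rows = self._frame([(f"n{i}", 0.5, 0.5, 0.5, 0.5) for i in range(6)])
        assert select_hubs(rows) == sorted(rows["node"])

    def test_star_center_is_a_hub(self):
        g = build_graph([("c", f"l{i}") for i in range(4)])
        hubs = select_hubs(centralities(g))
        assert "c" in hubs

    def test_exactly_the_two_doubly_ranked_nodes(self):
        # h1 tops in/out degree, h2 tops betweenness/eigenvector, the rest
        # top at most one metric
        rows = self._frame([
            ("h1", 0.9, 0.9, 0.1, 0.1),
            ("h2", 0.1, 0.1, 0.9, 0.9),
            ("x1", 0.8, 0.1, 0.1, 0.1),
            ("x2", 0.1, 0.8, 0.1, 0.1),
            ("x3", 0.1, 0.1, 0.8, 0.1),
            ("x4", 0.1, 0.1, 0.1, 0.8),
            ("x5", 0.2, 0.2, 0.2, 0.2),
            ("x6", 0.2, 0.2, 0.2, 0.2),
            ("x7", 0.2, 0.2, 0.2, 0.2),
            ("x8", 0.2, 0.2, 0.2, 0.2),
        ])
        assert select_hubs(rows) == ["h1", "h2"]

    def test_invariant_to_row_order(self):
        g = random_directed_graph(15, 60, seed=8)
        rows = centralities(g)
        shuffled = rows.sample(frac=1, random_state=1).reset_index(drop=True)
        assert select_hubs(rows) == select_hubs(shuffled)

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError):
            select_hubs(pd.DataFrame(columns=["node", "in_degree", "out_degree",
                                              "betweenness", "eigenvector"]))
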