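import itertools

import networkx as nx
import numpy as np
import pytest

from netfidelity.network_metrics import distance_profiles, graph_metrics, node_metrics


# ---------------------------------------------------------------------------
# independent brute-force oracles (no networkx)


def floyd_warshall(n, edges):
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for u, v in edges:
        d[u, v] = d[v, u] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d


def triangle_clustering(n, edges):
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = []
    for i in range(n):
        k = len(adj[i])
        if k < 2:
            out.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(sorted(adj[i]), 2)
                    if b in adj[a])
        out.append(2.0 * links / (k * (k - 1)))
    return out


def betweenness_by_path_counting(n, edges):
    """Betweenness from explicit shortest-path counts per source via BFS
    dynamic programming (independent of networkx)."""
    adj = [set() for _ in range(n)]
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = floyd_warshall(n, edges)
    # sigma[s][t]: number of shortest s-t paths
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s][s] = 1.0
        order = sorted((d, t) for t, d in enumerate(dist[s]) if np.isfinite(d))
        for d, t in order:
            if t == s:
                continue
            sigma[s][t] = sum(sigma[s][p] for p in adj[t]
                              if dist[s][p] == d - 1)
    btw = np.zeros(n)
    for s, t in itertools.permutations(range(n), 2):
        if not np.isfinite(dist[s][t]) or sigma[s][t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if dist[s][v] + dist[v][t] == dist[s][t]:
                btw[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    scale = 1.0 / ((n - 1) * (n - 2)) if n > 2 else 1.0
    return btw * scale


def random_graph(rng, n, p=0.25):
    edges = [(i, j) for i, j in itertools.combinations(range(n), 2)
             if rng.random() < p]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g, edges


class TestOracleEquivalence:
    def test_fifty_random_graphs(self):
        """Path length, clustering and betweenness agree with brute-force
        enumeration on 50 random graphs with n <= 20."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 21))
            g, edges = random_graph(rng, n)
            gm = graph_metrics(g)
            d = floyd_warshall(n, edges)
            finite = d[(d > 0) & np.isfinite(d)]
            if finite.size:
                assert gm["path_length"] == pytest.approx(finite.mean())
            else:
                assert np.isnan(gm["path_length"])
            table = node_metrics(g).set_index("unit")
            expect_c = triangle_clustering(n, edges)
            expect_b = betweenness_by_path_counting(n, edges)
            for v in range(n):
                assert table.loc[v, "clustering"] == pytest.approx(expect_c[v])
                assert table.loc[v, "betweenness"] == pytest.approx(expect_b[v])


class TestNodeMetrics:
    def test_triangle(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        t = node_metrics(g)
        assert (t["clustering"] == 1.0).all()
        assert (t["degree"] == 2).all()

    def test_star_center(self):
        g = nx.star_graph(3)
        t = node_metrics(g).set_index("unit")
        assert t.loc[0, "clustering"] == 0.0
        assert t.loc[0, "betweenness"] == t["betweenness"].max()
        assert t.loc[0, "betweenness"] > 0

    def test_one_of_three_neighbor_pairs_linked(self):
        """Node with 3 neighbors of which one pair is joined: C = 1/3."""
        g = nx.Graph([(0, 1), (0, 2), (0, 3), (1, 2)])
        t = node_metrics(g).set_index("unit")
        assert t.loc[0, "clustering"] == pytest.approx(1 / 3)

    def test_empty_graph_raises(self):
        with pytest.raises(ValueError):
            node_metrics(nx.Graph())


class TestGraphMetrics:
    def test_path_graph_length(self):
        g = nx.path_graph(3)
        assert graph_metrics(g)["path_length"] == pytest.approx(4 / 3)

    def test_complete_graph(self):
        g = nx.complete_graph(5)
        gm = graph_metrics(g)
        assert gm["density"] == pytest.approx(1.0)
        assert gm["path_length"] == pytest.approx(1.0)

    def test_star_density_and_assortativity(self):
        g = nx.star_graph(3)
        gm = graph_metrics(g)
        assert gm["density"] == pytest.approx(0.5)
        assert gm["assortativity"] < 0

    def test_unreachable_pairs_excluded_and_reported(self):
        g = nx.Graph([(0, 1), (2, 3)])
        gm = graph_metrics(g)
        assert gm["path_length"] == pytest.approx(1.0)
        assert gm["unreachable_pair_fraction"] == pytest.approx(4 / 6)

    def test_degree_conservation_directed(self):
        import networkx as nx_
        from netfidelity.functional_connectivity import FunctionalGraph
        d = nx_.MultiDiGraph()
        for node in range(4):
            d.add_node(node, x=float(node) * 500.0, y=0.0)
        for u, v in [(0, 1), (1, 0), (1, 2), (2, 3), (0, 2)]:
            d.add_edge(u, v, lag_ms=1.0, weight=0.5, distance_um=500.0)
        fg = FunctionalGraph(directed=d)
        t = node_metrics(fg)
        assert t["in_degree"].sum() == t["out_degree"].sum() == 5
        gm = graph_metrics(fg)
        assert gm["reciprocal_fraction"] == pytest.approx(2 / 5)


class TestDistanceProfiles:
    def _graph(self, edges):
        g = nx.Graph()
        for node in range(6):
            g.add_node(node, x=float(node % 3) * 500.0,
                       y=float(node // 3) * 500.0)
        for u, v in edges:
            g.add_edge(u, v, weight=0.5)
        return g

    def test_nearest_neighbor_only(self):
        g = self._graph([(0, 1), (1, 2), (3, 4), (4, 5), (0, 3), (1, 4), (2, 5)])
        prof = distance_profiles(g, None, bin_um=100.0)
        occupied = prof.set_index("bin_center_um")
        assert occupied.loc[550.0, "p_connect"] == pytest.approx(1.0)
        beyond = prof[prof.bin_center_um > 600]
        assert (beyond["p_connect"] == 0).all()

    def test_complete_graph_probability_one(self):
        import itertools as it
        g = self._graph(list(it.combinations(range(6), 2)))
        prof = distance_profiles(g, None)
        assert (prof["p_connect"] == 1.0).all()
        assert prof.attrs["mean_connection_length_um"] > 0
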