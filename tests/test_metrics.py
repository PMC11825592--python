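"""Degree, Brandes betweenness, and density integration."""

import itertools

import numpy as np
import pytest

from connectocentric import (
    CentralityProfile,
    betweenness_centrality,
    centrality_profile,
    density_sweep,
    integrate_across_densities,
    node_degree,
    process_connectome,
    subject_centrality,
)
from connectocentric.metrics import _brandes, integrated_degree
from connectocentric.processing import ProcessedNetwork, ThresholdedNetwork

from conftest import make_connectome


def adjacency_from_edges(n, edges):
    adj = np.zeros((n, n), dtype=np.int8)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return adj


def tnet(adj):
    n = adj.shape[0]
    return ThresholdedNetwork(
        labels=tuple(f"n{i}" for i in range(n)),
        adjacency=adj,
        density=1.0,
        edge_count=int(adj.sum() // 2),
    )


def betweenness_oracle(adj):
    """Brute force: enumerate every shortest path between every pair.

    BFS distances; shortest paths enumerated recursively through the
    predecessor DAG. Each unordered pair contributes the fraction of its
    geodesics passing through each interior node.
    """
    n = adj.shape[0]
    bc = np.zeros(n)

    def bfs(s):
        dist = {s: 0}
        frontier = [s]
        while frontier:
            nxt = []
            for v in frontier:
                for w in np.flatnonzero(adj[v]):
                    if w not in dist:
                        dist[int(w)] = dist[v] + 1
                        nxt.append(int(w))
            frontier = nxt
        return dist

    def all_paths(s, t, dist):
        if s == t:
            return [[t]]
        paths = []
        for v in np.flatnonzero(adj[:, t]):
            v = int(v)
            if v in dist and dist[v] == dist[t] - 1:
                paths.extend(p + [t] for p in all_paths(s, v, dist))
        return paths

    for s, t in itertools.combinations(range(n), 2):
        dist = bfs(s)
        if t not in dist:
            continue
        paths = all_paths(s, t, dist)
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


class TestDegree:
    def test_empty_graph(self):
        assert np.all(node_degree(tnet(np.zeros((5, 5), dtype=np.int8))) == 0)

    def test_complete_graph(self):
        adj = np.ones((4, 4), dtype=np.int8) - np.eye(4, dtype=np.int8)
        assert np.all(node_degree(tnet(adj)) == 3)

    def test_star(self):
        adj = adjacency_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        np.testing.assert_array_equal(node_degree(tnet(adj)), [3, 1, 1, 1])


class TestBetweenness:
    def test_complete_graph_is_zero(self):
        for n in (3, 5, 8):
            adj = np.ones((n, n), dtype=np.int8) - np.eye(n, dtype=np.int8)
            assert np.all(betweenness_centrality(tnet(adj)) == 0)

    def test_path_p3(self):
        adj = adjacency_from_edges(3, [(0, 1), (1, 2)])
        np.testing.assert_allclose(betweenness_centrality(tnet(adj)), [0, 1, 0])

    def test_cycle_c4_splits_geodesics(self):
        adj = adjacency_from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0)])
        np.testing.assert_allclose(betweenness_centrality(tnet(adj)), [0.5] * 4)

    def test_matches_bruteforce_on_random_graphs(self):
        """Brandes equals explicit shortest-path enumeration, n <= 7."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = int(rng.integers(3, 8))
            p = rng.uniform(0.25, 0.9)
            adj = (rng.random((n, n)) < p).astype(np.int8)
            adj = np.triu(adj, 1)
            adj = adj + adj.T  # possibly disconnected: also covered
            np.testing.assert_allclose(
                _brandes(adj), betweenness_oracle(adj), atol=1e-9
            )

    def test_matches_networkx_unnormalized(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 15
            adj = (rng.random((n, n)) < 0.3).astype(np.int8)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            ref = nx.betweenness_centrality(
                nx.from_numpy_array(adj), normalized=False
            )
            np.testing.assert_allclose(
                _brandes(adj), [ref[i] for i in range(n)], atol=1e-9
            )


class TestIntegration:
    def test_constant_profile(self):
        labels = ("a", "b")
        values = np.full((21, 2), 3.0)
        prof = CentralityProfile("degree", values, tuple(range(20, 41)), labels)
        np.testing.assert_allclose(
            integrate_across_densities(prof).values, [63.0, 63.0]
        )

    def test_arithmetic_series(self):
        values = np.arange(1, 22, dtype=float)[:, None]
        prof = CentralityProfile("degree", values, tuple(range(20, 41)), ("a",))
        assert integrate_across_densities(prof).values[0] == 231

    def test_single_density_is_identity(self):
        prof = CentralityProfile("degree", [[5.0, 2.0]], (20,), ("a", "b"))
        np.testing.assert_allclose(
            integrate_across_densities(prof).values, [5.0, 2.0]
        )

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            CentralityProfile("degree", np.zeros((0, 2)), (), ("a", "b"))

    def test_complete_graph_integrals(self):
        # all weights positive and distinct: at every density the graph is
        # the top-k graph, and at 100% it is complete
        n = 8
        rng = np.random.default_rng(8)
        w = np.zeros((n, n))
        iu, ju = np.triu_indices(n, 1)
        w[iu, ju] = rng.permutation(len(iu)) + 1.0
        w = w + w.T
        net = ProcessedNetwork(tuple(f"n{i}" for i in range(n)), w)
        prof_bc = centrality_profile(net, "betweenness", 100, 100)
        assert np.all(prof_bc.values == 0)
        prof_deg = centrality_profile(net, "degree", 100, 100)
        assert np.all(prof_deg.values == n - 1)


class TestProfileConsistency:
    """The incremental sweep equals independent per-density thresholding."""

    def test_profile_matches_per_density_recomputation(self):
        rng = np.random.default_rng(21)
        counts = rng.integers(0, 200, (15, 15))
        np.fill_diagonal(counts, 0)
        conn = make_connectome(counts, waytotals=rng.uniform(100, 500, 15))
        net = process_connectome(conn)
        nets = density_sweep(net, 20, 40, 5)
        prof_deg = centrality_profile(net, "degree", 20, 40, 5)
        prof_bc = centrality_profile(net, "betweenness", 20, 40, 5)
        for row, t in enumerate(nets):
            np.testing.assert_array_equal(prof_deg.values[row], node_degree(t))
            np.testing.assert_allclose(
                prof_bc.values[row], betweenness_centrality(t), atol=1e-9
            )
        np.testing.assert_allclose(
            integrated_degree(net, 20, 40, 5),
            integrate_across_densities(prof_deg).values,
        )

    def test_degree_rows_monotone_across_sweep(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 100, (12, 12))
        np.fill_diagonal(counts, 0)
        conn = make_connectome(counts)
        prof = centrality_profile(process_connectome(conn), "degree")
        assert np.all(np.diff(prof.values, axis=0) >= 0)


class TestSubjectCentrality:
    def test_deterministic_and_right_shape(self, small_cohort):
        conn = small_cohort.connectomes[0]
        a = subject_centrality(conn)
        b = subject_centrality(conn)
        assert len(a.degree.values) == conn.n_nodes
        np.testing.assert_array_equal(a.degree.values, b.degree.values)
        np.testing.assert_array_equal(a.betweenness.values, b.betweenness.values)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 300, (14, 14))
        np.fill_diagonal(counts, 0)
        conn = make_connectome(counts, waytotals=rng.uniform(200, 900, 14))
        perm = rng.permutation(14)
        conn_p = make_connectome(
            counts[np.ix_(perm, perm)],
            waytotals=conn.waytotals[perm],
            labels=tuple(conn.labels[i] for i in perm),
        )
        sc = subject_centrality(conn, low=20, high=40, step=5)
        sc_p = subject_centrality(conn_p, low=20, high=40, step=5)
        np.testing.assert_allclose(sc_p.degree.values, sc.degree.values[perm])
        np.testing.assert_allclose(
            sc_p.betweenness.values, sc.betweenness.values[perm], atol=1e-9
        )

    def test_unknown_metric_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            subject_centrality(small_cohort.connectomes[0], metrics=("clustering",))
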