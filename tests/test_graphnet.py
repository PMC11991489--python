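"""Binary graph metrics against brute-force and networkx oracles."""

import networkx as nx
import numpy as np
import pytest

from myocortex import (
    char_path_length,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    metrics_over_sparsity,
    random_null,
    small_world_sigma,
    threshold_by_sparsity,
)
from myocortex.graphnet import GraphError, double_edge_swap


# -- independent brute-force oracles (pure python BFS) ----------------------

def bfs_distances(a):
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if a[u, v] and v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def brute_clustering(a):
    n = a.shape[0]
    vals = []
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(a[u, v] for u in nb for v in nb if u < v)
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def brute_global_eff(a):
    n = a.shape[0]
    d = bfs_distances(a)
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]))
    return total / (n * (n - 1))


def brute_local_eff(a):
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if a[i, j]]
        k = len(nb)
        if k < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        d = bfs_distances(sub)
        s = sum(1.0 / d[u, v] for u in range(k) for v in range(k)
                if u != v and np.isfinite(d[u, v]))
        total += s / (k * (k - 1))
    return total / n


def brute_char_path(a):
    d = bfs_distances(a)
    n = a.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


class TestMetricOracles:
    def test_all_metrics_match_brute_force_on_random_graphs(self):
        """C, L, E_g, E_loc equal exhaustive BFS values on 50 graphs of <= 13 nodes."""
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 14))
            p = float(rng.uniform(0.15, 0.7))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            a = nx.to_numpy_array(g)
            if g.number_of_edges() == 0:
                continue
            assert clustering_coefficient(a) == pytest.approx(brute_clustering(a), abs=1e-12)
            assert global_efficiency(a) == pytest.approx(brute_global_eff(a), abs=1e-12)
            assert local_efficiency(a) == pytest.approx(brute_local_eff(a), abs=1e-12)
            assert char_path_length(a) == pytest.approx(brute_char_path(a), abs=1e-12)
            checked += 1

    def test_complete_graph(self):
        a = np.ones((13, 13)) - np.eye(13)
        assert clustering_coefficient(a) == 1.0
        assert char_path_length(a) == 1.0
        assert global_efficiency(a) == 1.0

    def test_star_graph(self):
        a = nx.to_numpy_array(nx.star_graph(8))
        assert clustering_coefficient(a) == 0.0
        assert local_efficiency(a) == 0.0

    def test_path_graph_global_efficiency(self):
        # 1-2-3: ordered-pair distances {1,1,1,1,2,2} -> E_g = (4 + 1)/6
        a = nx.to_numpy_array(nx.path_graph(3))
        assert global_efficiency(a) == pytest.approx(5.0 / 6.0)

    def test_complete_k4_local_efficiency(self):
        a = np.ones((4, 4)) - np.eye(4)
        assert local_efficiency(a) == pytest.approx(1.0)

    def test_edgeless_char_path_flagged(self):
        with pytest.raises(GraphError):
            char_path_length(np.zeros((5, 5)))

    def test_networkx_cross_check_larger_graph(self):
        g = nx.gnp_random_graph(50, 0.1, seed=3)
        a = nx.to_numpy_array(g)
        assert clustering_coefficient(a) == pytest.approx(nx.average_clustering(g))
        assert global_efficiency(a) == pytest.approx(nx.global_efficiency(g))


class TestThreshold:
    def symmetric_weights(self, rng, n=13):
        w = rng.uniform(0, 1, (n, n))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 1.0)
        return w

    def test_edge_count_at_paper_sparsity(self, rng):
        # N=13: round(0.22 * 78) = 17 edges
        a = threshold_by_sparsity(self.symmetric_weights(rng), 0.22)
        assert a.sum() // 2 == 17

    def test_all_equal_weights_tiebreak_exact_count(self):
        w = np.ones((13, 13))
        a = threshold_by_sparsity(w, 0.25)
        assert a.sum() // 2 == round(0.25 * 78)

    def test_sparsity_one_complete(self, rng):
        a = threshold_by_sparsity(self.symmetric_weights(rng), 1.0)
        assert a.sum() // 2 == 78

    def test_keeps_strongest_edges(self, rng):
        w = self.symmetric_weights(rng)
        a = threshold_by_sparsity(w, 0.1)
        iu, ju = np.triu_indices(13, k=1)
        kept = w[iu, ju][a[iu, ju] == 1]
        dropped = w[iu, ju][a[iu, ju] == 0]
        assert kept.min() >= dropped.max()

    def test_zero_edges_refused(self, rng):
        with pytest.raises(GraphError):
            threshold_by_sparsity(self.symmetric_weights(rng), 0.001)

    def test_deterministic(self, rng):
        w = self.symmetric_weights(rng)
        assert np.array_equal(threshold_by_sparsity(w, 0.25), threshold_by_sparsity(w, 0.25))


class TestNullEnsemble:
    def test_degree_sequence_preserved(self, rng):
        a = nx.to_numpy_array(nx.watts_strogatz_graph(30, 4, 0.2, seed=1))
        deg = a.sum(axis=1)
        for _ in range(5):
            b = double_edge_swap(a, 100 * int(a.sum() // 2), np.random.default_rng(rng.integers(1 << 30)))
            assert np.array_equal(b.sum(axis=1), deg)
            assert np.array_equal(b, b.T)
            assert np.all(np.diag(b) == 0)

    def test_complete_graph_rigid(self):
        a = np.ones((6, 6)) - np.eye(6)
        null = random_null(a, n_random=5, seed=0)
        res = small_world_sigma(a, n_random=5, seed=0)
        assert null.degenerate
        assert res["sigma"] == pytest.approx(1.0)

    def test_small_world_clustering_exceeds_null(self):
        a = nx.to_numpy_array(nx.watts_strogatz_graph(100, 6, 0.1, seed=2))
        null = random_null(a, n_random=20, seed=0)
        assert clustering_coefficient(a) > 2 * null.c_random


class TestMetricsOverSparsity:
    def test_eight_levels_and_definitional_sigma(self, rng):
        w = TestThreshold().symmetric_weights(rng)
        res = metrics_over_sparsity(w, n_random=10, seed=0)
        assert len(res["levels"]) == 8
        for lv in res["levels"]:
            assert lv["sigma"] == pytest.approx(lv["gamma"] / lv["lambda"], rel=1e-12)
            assert 0.0 <= lv["E_g"] <= 1.0
            assert 0.0 <= lv["E_loc"] <= 1.0

    def test_global_efficiency_monotone_in_sparsity(self, rng):
        w = TestThreshold().symmetric_weights(rng)
        res = metrics_over_sparsity(w, n_random=2, seed=0)
        eg = [lv["E_g"] for lv in res["levels"]]
        assert np.all(np.diff(eg) >= -1e-12)

    def test_adding_edges_never_lowers_global_efficiency(self, rng):
        g = nx.gnp_random_graph(13, 0.2, seed=5)
        a = nx.to_numpy_array(g)
        base = global_efficiency(a)
        iu, ju = np.where(np.triu(1 - a, k=1))
        for k in rng.choice(len(iu), size=min(10, len(iu)), replace=False):
            b = a.copy()
            b[iu[k], ju[k]] = b[ju[k], iu[k]] = 1
            assert global_efficiency(b) >= base - 1e-12
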