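import itertools

import networkx as nx
import numpy as np
import pytest

import morphnet as mn
from conftest import random_connected_adjacency


def _adj(edges, n):
    A = np.zeros((n, n), dtype=bool)
    for i, j in edges:
        A[i, j] = A[j, i] = True
    return A


def complete(n):
    A = np.ones((n, n), dtype=bool)
    np.fill_diagonal(A, False)
    return A


def ring(n):
    return _adj([(i, (i + 1) % n) for i in range(n)], n)


def path(n):
    return _adj([(i, i + 1) for i in range(n - 1)], n)


def brute_clustering(A):
    n = A.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if A[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        t = sum(1 for a, b in itertools.combinations(nbrs, 2) if A[a, b])
        cs.append(2.0 * t / (k * (k - 1)))
    return float(np.mean(cs))


def brute_distances(A):
    n = A.shape[0]
    D = np.full((n, n), np.inf)
    for s in range(n):
        D[s, s] = 0
        frontier, d = [s], 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if A[u, v] and v not in seen:
                        seen.add(v)
                        D[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return D


class TestGraphIdentities:
    @pytest.mark.parametrize("n", [3, 4, 7])
    def test_complete_graph(self, n):
        A = complete(n)
        assert mn.clustering_coefficient(A) == 1.0
        assert mn.characteristic_path_length(A) == 1.0
        assert np.all(mn.nodal_efficiency(A) == 1.0)

    def test_ring_c5(self):
        A = ring(5)
        assert mn.clustering_coefficient(A) == 0.0
        assert mn.characteristic_path_length(A) == 1.5

    def test_path_p3(self):
        A = path(3)
        assert mn.characteristic_path_length(A) == pytest.approx(4 / 3)
        assert mn.nodal_efficiency(A, 0) == pytest.approx(0.75)  # (1 + 1/2)/2
        assert mn.nodal_efficiency(A, 1) == pytest.approx(1.0)

    def test_star_s5_leaf(self):
        A = _adj([(0, i) for i in range(1, 5)], 5)
        assert mn.nodal_efficiency(A, 1) == pytest.approx((1 + 3 * 0.5) / 4)

    def test_disconnected_graph_is_hard_error(self):
        A = _adj([(0, 1)], 4)
        with pytest.raises(mn.DisconnectedGraphError):
            mn.characteristic_path_length(A)
        with pytest.raises(mn.DisconnectedGraphError):
            mn.nodal_efficiency(A)


class TestBruteForceAgreement:
    def test_random_12_node_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = random_connected_adjacency(rng, 12, p=0.3)
            D = brute_distances(A)
            assert mn.clustering_coefficient(A) == pytest.approx(
                brute_clustering(A), abs=1e-12)
            off = D[np.triu_indices(12, 1)]
            assert mn.characteristic_path_length(A) == pytest.approx(
                off.mean(), abs=1e-12)
            with np.errstate(divide="ignore"):
                inv = 1.0 / D
            np.fill_diagonal(inv, 0.0)
            assert np.allclose(mn.nodal_efficiency(A), inv.sum(1) / 11, atol=1e-12)

    def test_agreement_with_networkx(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            A = random_connected_adjacency(rng, 15, p=0.25)
            G = nx.from_numpy_array(A.astype(int))
            assert mn.clustering_coefficient(A) == pytest.approx(
                nx.average_clustering(G), abs=1e-12)
            assert mn.characteristic_path_length(A) == pytest.approx(
                nx.average_shortest_path_length(G), abs=1e-12)

    def test_efficiency_monotone_under_edge_deletion(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            A = random_connected_adjacency(rng, 12, p=0.5)
            E = mn.nodal_efficiency(A)
            edges = np.argwhere(np.triu(A, 1))
            i, j = edges[rng.integers(len(edges))]
            B = A.copy()
            B[i, j] = B[j, i] = False
            import scipy.sparse as sp
            import scipy.sparse.csgraph as csg
            if csg.connected_components(sp.csr_matrix(B))[0] != 1:
                continue
            assert np.all(mn.nodal_efficiency(B) <= E + 1e-12)


class TestRewiring:
    def test_degree_sequence_and_simplicity_preserved(self):
        rng = np.random.default_rng(3)
        A = random_connected_adjacency(rng, 20, p=0.25)
        null = mn.rewire_null(A, seed=5)
        assert np.all(null.sum(1) == A.sum(1))
        assert not np.any(np.diag(null))
        assert np.all(null == null.T)
        assert np.any(null != A)  # actually randomized

    def test_null_stays_connected(self):
        import scipy.sparse as sp
        import scipy.sparse.csgraph as csg
        rng = np.random.default_rng(4)
        A = random_connected_adjacency(rng, 20, p=0.15)
        for s in range(5):
            null = mn.rewire_null(A, seed=s)
            assert csg.connected_components(sp.csr_matrix(null))[0] == 1

    def test_complete_graph_returned_unchanged(self):
        A = complete(4)
        assert np.array_equal(mn.rewire_null(A, seed=0), A)

    def test_randomization_destroys_planted_clustering(self):
        # caveman-style planted triangles: nulls should have lower Cp on average
        blocks = [_adj(list(itertools.combinations(range(5 * b, 5 * b + 5), 2)), 20)
                  for b in range(4)]
        A = np.zeros((20, 20), dtype=bool)
        for B in blocks:
            A |= B
        for b in range(4):  # ring of cliques to stay connected
            i, j = 5 * b, (5 * b + 5) % 20
            A[i, j] = A[j, i] = True
        cp = mn.clustering_coefficient(A)
        null_cp = [mn.clustering_coefficient(mn.rewire_null(A, seed=s))
                   for s in range(20)]
        assert np.mean(null_cp) < cp


class TestSmallWorldNormalization:
    def test_identity_normalization_on_swapless_graph(self):
        # complete graphs admit no swap, so every "null" equals the input
        zcp, zlp = mn.normalize_small_world(complete(5), n_null=4, seed=0)
        assert (zcp, zlp) == (1.0, 1.0)

    def test_lattice_has_elevated_normalized_clustering(self):
        G = nx.watts_strogatz_graph(24, 6, 0.0, seed=1)  # pure ring lattice
        A = nx.to_numpy_array(G).astype(bool)
        zcp, _ = mn.normalize_small_world(A, n_null=20, seed=2)
        assert zcp > 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        A = random_connected_adjacency(rng, 18, p=0.25)
        a = mn.normalize_small_world(A, n_null=10, seed=123)
        b = mn.normalize_small_world(A, n_null=10, seed=123)
        assert a == b

    def test_zscore_mode(self):
        rng = np.random.default_rng(7)
        A = random_connected_adjacency(rng, 18, p=0.3)
        zcp, zlp = mn.normalize_small_world(A, n_null=10, seed=1, mode="zscore")
        assert np.isfinite(zcp) and np.isfinite(zlp)


class TestAucOverSparsity:
    def test_constant_returns_value(self):
        grid = mn.default_sparsity_grid()
        assert mn.auc_over_sparsity(np.full(grid.size, 3.3), grid) == pytest.approx(3.3)

    def test_identity_on_unit_grid(self):
        g = np.linspace(0, 1, 11)
        assert mn.auc_over_sparsity(g, g) == pytest.approx(0.5)

    def test_matches_hand_trapezoid(self):
        rng = np.random.default_rng(8)
        g = np.sort(rng.random(9))
        v = rng.random(9)
        hand = sum((v[i] + v[i + 1]) / 2 * (g[i + 1] - g[i]) for i in range(8))
        assert mn.auc_over_sparsity(v, g) == pytest.approx(
            hand / (g[-1] - g[0]), abs=1e-12)

    def test_single_level_returns_value(self):
        assert mn.auc_over_sparsity([2.5], [0.1]) == 2.5
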