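import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon

import morphnet as mn
from morphnet.similarity import GridMismatchError, maximum_spanning_edges, \
    round_half_away


def _rand_dist(rng, g):
    p = rng.random(g)
    return p / p.sum()


class TestJsd:
    def test_identity_is_zero(self):
        rng = np.random.default_rng(0)
        p = _rand_dist(rng, 28)
        assert mn.jsd(p, p) == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_support_reaches_base2_bound(self):
        assert mn.jsd([1.0, 0.0], [0.0, 1.0]) == pytest.approx(1.0, abs=1e-9)

    def test_hand_evaluated_value(self):
        # 0.5*KL(p||m) + 0.5*KL(q||m) with p=(.5,.5), q=(1,0), m=(.75,.25):
        # = 0.5*(0.5*log2(2/3) + 0.5*log2(2)) + 0.5*log2(4/3) = 0.311278...
        assert mn.jsd([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.31128, abs=5e-6)

    def test_matches_scipy_independent_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p, q = _rand_dist(rng, 28), _rand_dist(rng, 28)
            assert mn.jsd(p, q) == pytest.approx(
                jensenshannon(p, q, base=2) ** 2, abs=1e-10)

    def test_symmetry_bounds_and_metric_sqrt(self):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            p, q, r = (_rand_dist(rng, 12) for _ in range(3))
            d_pq, d_qr, d_pr = mn.jsd(p, q), mn.jsd(q, r), mn.jsd(p, r)
            assert d_pq == pytest.approx(mn.jsd(q, p), abs=1e-12)
            assert 0.0 <= d_pq <= 1.0
            # the square root of base-2 JSD is a metric
            assert np.sqrt(d_pr) <= np.sqrt(d_pq) + np.sqrt(d_qr) + 1e-12

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), g=st.integers(2, 64))
    def test_divergence_properties_hold_for_arbitrary_distributions(self, seed, g):
        rng = np.random.default_rng(seed)
        p, q = _rand_dist(rng, g), _rand_dist(rng, g)
        d = mn.jsd(p, q)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(mn.jsd(q, p), abs=1e-12)
        assert mn.jsd(p, p) <= 1e-9

    def test_grid_mismatch_rejected(self):
        a = mn.estimate_density(np.arange(10.0), grid_size=8)
        b = mn.estimate_density(np.arange(10.0) + 30, grid_size=8)
        with pytest.raises(GridMismatchError):
            mn.jsd(a, b)
        with pytest.raises(GridMismatchError):
            mn.jsd([0.5, 0.5], [0.2, 0.3, 0.5])


def _toy_map(rng, n_roi, n_vert=40, locs=None, scale=1.0):
    labels = np.repeat(np.arange(1, n_roi + 1), n_vert)
    locs = np.zeros(n_roi) if locs is None else np.asarray(locs, float)
    values = np.repeat(locs, n_vert) + scale * rng.standard_normal(labels.size)
    return mn.VertexFeatureMap("sub-001", "CT", values, labels)


class TestBuildSimilarity:
    def test_identical_rois_have_weight_one(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=50)
        values = np.concatenate([v, v])
        labels = np.repeat([1, 2], 50)
        S = mn.build_similarity(mn.VertexFeatureMap("s", "CT", values, labels))
        assert S.weights[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_value_ranges_give_weight_near_zero(self):
        rng = np.random.default_rng(4)
        values = np.concatenate([rng.normal(0, 1e-3, 50),
                                 rng.normal(100, 1e-3, 50)])
        labels = np.repeat([1, 2], 50)
        S = mn.build_similarity(mn.VertexFeatureMap("s", "CT", values, labels))
        assert S.weights[0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_matrix_equals_elementwise_jsd_recomputation(self):
        rng = np.random.default_rng(5)
        vmap = _toy_map(rng, 10, locs=rng.normal(size=10))
        S = mn.build_similarity(vmap, grid_size=28)
        for i, j in itertools.combinations(range(10), 2):
            vi, vj = vmap.roi_values(i + 1), vmap.roi_values(j + 1)
            lo = min(vi.min(), vj.min())
            hi = max(vi.max(), vj.max())
            p = mn.estimate_density(vi, 28, grid_range=(lo, hi))
            q = mn.estimate_density(vj, 28, grid_range=(lo, hi))
            assert S.weights[i, j] == pytest.approx(1.0 - mn.jsd(p, q), abs=1e-12)

    def test_missing_roi_listed_in_error(self):
        vmap = _toy_map(np.random.default_rng(6), 4)
        with pytest.raises(Exception, match=r"\[5, 6\]"):
            mn.build_similarity(vmap, roi_ids=[1, 2, 3, 4, 5, 6])

    def test_relabelling_equivariance(self):
        rng = np.random.default_rng(7)
        n = 6
        vmap = _toy_map(rng, n, locs=rng.normal(size=n))
        S = mn.build_similarity(vmap)
        perm = np.random.default_rng(8).permutation(n)
        # relabel ROI k+1 -> position of k in perm, +1
        new_labels = np.empty_like(vmap.roi_labels)
        inv = np.argsort(perm)
        for old in range(n):
            new_labels[vmap.roi_labels == old + 1] = inv[old] + 1
        S2 = mn.build_similarity(
            mn.VertexFeatureMap("s", "CT", vmap.values, new_labels))
        assert np.allclose(S2.weights[np.ix_(inv, inv)], S.weights, atol=1e-12)

    def test_sqrt_variant_and_global_grid_policy(self):
        rng = np.random.default_rng(9)
        vmap = _toy_map(rng, 5, locs=rng.normal(size=5))
        S1 = mn.build_similarity(vmap, variant="one_minus_sqrt_jsd")
        S0 = mn.build_similarity(vmap)
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(1 - S1.weights[off], np.sqrt(1 - S0.weights[off]),
                           atol=1e-12)
        Sg = mn.build_similarity(vmap, grid_policy="subject_global")
        assert np.max(np.abs(Sg.weights - Sg.weights.T)) < 1e-12


def _bruteforce_max_spanning_tree(W):
    """Exhaustive search over all spanning trees of a complete weighted graph."""
    import scipy.sparse as sp
    import scipy.sparse.csgraph as csg

    n = W.shape[0]
    edges = list(itertools.combinations(range(n), 2))
    best, best_w = None, -np.inf
    for tree in itertools.combinations(edges, n - 1):
        A = np.zeros((n, n))
        for i, j in tree:
            A[i, j] = A[j, i] = 1
        if csg.connected_components(sp.csr_matrix(A))[0] != 1:
            continue
        w = sum(W[i, j] for i, j in tree)
        if w > best_w:
            best_w, best = w, set(tree)
    return best


class TestThresholdEnsemble:
    def test_edge_counts_connectivity_and_nesting(self):
        import scipy.sparse as sp
        import scipy.sparse.csgraph as csg

        rng = np.random.default_rng(10)
        n = 20
        W = rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        S = mn.SimilarityMatrix("s", "CT", W, np.arange(1, n + 1))
        grid = mn.default_sparsity_grid()
        ens = mn.threshold_ensemble(S, grid)
        prev = None
        for s, A in zip(grid, ens.adjacencies):
            expected = max(n - 1, round_half_away(s * n * (n - 1) / 2))
            assert int(A.sum()) // 2 == expected
            assert csg.connected_components(sp.csr_matrix(A))[0] == 1
            if prev is not None:
                assert np.all(A[prev])  # nested edge sets
            prev = A

    def test_full_sparsity_gives_complete_graph(self):
        rng = np.random.default_rng(11)
        n = 8
        W = rng.random((n, n)); W = (W + W.T) / 2; np.fill_diagonal(W, 1.0)
        S = mn.SimilarityMatrix("s", "CT", W, np.arange(1, n + 1))
        ens = mn.threshold_ensemble(S, [1.0])
        assert int(ens.adjacencies[0].sum()) // 2 == n * (n - 1) // 2

    def test_mst_matches_exhaustive_search(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            n = 5
            W = rng.random((n, n)); W = (W + W.T) / 2; np.fill_diagonal(W, 1.0)
            tree = set(maximum_spanning_edges(W))
            brute = _bruteforce_max_spanning_tree(W)
            # weights are continuous so the optimum is unique a.s.
            assert tree == brute

    def test_minimal_sparsity_keeps_backbone_for_distance_decaying_weights(self):
        # weights strictly decreasing with |i - j|: the path 0-1-2-3-4 is the
        # unique maximum-weight spanning tree
        n = 5
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    W[i, j] = 1.0 - 0.2 * abs(i - j)
        np.fill_diagonal(W, 1.0)
        S = mn.SimilarityMatrix("s", "CT", W, np.arange(1, n + 1))
        ens = mn.threshold_ensemble(S, [0.01])  # below n-1 edges -> tree only
        A = ens.adjacencies[0]
        assert int(A.sum()) // 2 == n - 1
        expected = {(i, i + 1) for i in range(n - 1)}
        got = {(i, j) for i, j in zip(*np.triu_indices(n, 1)) if A[i, j]}
        assert got == expected

    def test_round_half_away_from_zero(self):
        assert round_half_away(658.35) == 658
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3
        assert round_half_away(877.8) == 878
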