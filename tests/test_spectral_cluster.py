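import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from gnnsc import (
    cluster_rows,
    gaussian_similarity,
    normalized_laplacian,
    partition_graph,
    spectral_embed,
)
from gnnsc.gnn import NodeEmbeddings
from gnnsc.graph_build import GeneGraph
from gnnsc.spectral_cluster import SimilarityMatrix


def _emb(vectors):
    vectors = np.asarray(vectors, float)
    return NodeEmbeddings(nodes=tuple(f"n{i}" for i in range(len(vectors))), vectors=vectors)


def _two_clouds(n_per=30, sep=10.0, jitter=1e-3, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(scale=jitter, size=(n_per, dim))
    b = rng.normal(scale=jitter, size=(n_per, dim))
    b[:, 0] += sep
    return _emb(np.vstack([a, b])), np.array([0] * n_per + [1] * n_per)


class TestGaussianSimilarity:
    def test_identical_embeddings_entry_one(self):
        sim = gaussian_similarity(_emb([[1.0, 2], [1.0, 2]]), omega=1.0)
        np.testing.assert_allclose(sim.W, 1.0)

    def test_distance_omega_sqrt2_gives_exp_minus_one(self):
        omega = 0.7
        d = omega * np.sqrt(2)
        sim = gaussian_similarity(_emb([[0.0], [d]]), omega=omega)
        assert sim.W[0, 1] == pytest.approx(np.exp(-1), abs=1e-12)

    def test_large_omega_limit_all_ones(self):
        sim = gaussian_similarity(_emb([[0.0], [3.0], [7.0]]), omega=1e9)
        np.testing.assert_allclose(sim.W, 1.0, atol=1e-12)

    def test_auto_omega_is_median_pairwise_distance(self):
        emb = _emb([[0.0], [1.0], [3.0]])  # distances 1, 2, 3 -> median 2
        sim = gaussian_similarity(emb)
        assert sim.omega == pytest.approx(2.0)

    def test_diagonal_is_one_and_symmetric(self):
        rng = np.random.default_rng(1)
        sim = gaussian_similarity(_emb(rng.normal(size=(10, 3))))
        np.testing.assert_allclose(np.diag(sim.W), 1.0)
        np.testing.assert_allclose(sim.W, sim.W.T)
        assert (sim.W > 0).all() and (sim.W <= 1).all()

    def test_invalid_omega_rejected(self):
        with pytest.raises(ValueError):
            gaussian_similarity(_emb([[0.0], [1.0]]), omega=-1.0)


class TestLaplacian:
    def test_two_by_two_hand_value(self):
        sim = SimilarityMatrix(nodes=("a", "b"), W=np.ones((2, 2)), omega=1.0)
        L = normalized_laplacian(sim)
        np.testing.assert_allclose(L, [[0.5, -0.5], [-0.5, 0.5]], atol=1e-12)
        np.testing.assert_allclose(np.linalg.eigvalsh(L), [0.0, 1.0], atol=1e-12)

    def test_smallest_eigenpair_is_zero_with_sqrt_degree_vector(self):
        rng = np.random.default_rng(2)
        sim = gaussian_similarity(_emb(rng.normal(size=(12, 3))))
        L = normalized_laplacian(sim)
        vals, vecs = np.linalg.eigh(L)
        assert vals[0] == pytest.approx(0.0, abs=1e-10)
        d_sqrt = np.sqrt(sim.W.sum(axis=1))
        d_sqrt /= np.linalg.norm(d_sqrt)
        cos = abs(d_sqrt @ vecs[:, 0])
        assert cos == pytest.approx(1.0, abs=1e-8)

    def test_block_diagonal_gives_zero_eigenvalue_multiplicity_two(self):
        # clouds so far apart the off-block kernel underflows to exactly 0
        emb, _ = _two_clouds(n_per=5, sep=1e4, jitter=1e-4)
        sim = gaussian_similarity(emb, omega=1.0)
        vals = np.linalg.eigvalsh(normalized_laplacian(sim))
        assert (np.abs(vals[:2]) < 1e-10).all() and vals[2] > 1e-6


class TestSpectralEmbed:
    def test_mu_one_single_zero_eigenvector_shares_sign(self):
        rng = np.random.default_rng(3)
        sim = gaussian_similarity(_emb(rng.normal(size=(8, 2))))
        se = spectral_embed(sim, mu=1, row_normalize=False)
        assert se.eigenvalues[0] == pytest.approx(0.0, abs=1e-10)
        col = se.U[:, 0]
        assert (col > 0).all() or (col < 0).all()
        assert (col > 0).any()  # sign convention: largest-magnitude entry positive

    def test_mu_equals_n_gives_full_ascending_spectrum(self):
        rng = np.random.default_rng(4)
        sim = gaussian_similarity(_emb(rng.normal(size=(7, 2))))
        se = spectral_embed(sim, mu=7, row_normalize=False)
        assert len(se.eigenvalues) == 7
        assert (np.diff(se.eigenvalues) >= -1e-12).all()
        assert (se.eigenvalues >= -1e-8).all() and (se.eigenvalues <= 2 + 1e-8).all()
        # columns orthonormal before row normalization
        np.testing.assert_allclose(se.U.T @ se.U, np.eye(7), atol=1e-8)

    def test_two_separated_clouds_rows_separate(self):
        emb, labels = _two_clouds(n_per=10, seed=5)
        se = spectral_embed(gaussian_similarity(emb), mu=2)
        got = cluster_rows(se, 2, seed=0)
        assert adjusted_rand_score(labels, got) == 1.0

    def test_mu_out_of_range_rejected(self):
        sim = gaussian_similarity(_emb([[0.0], [1.0]]))
        for mu in (0, 3):
            with pytest.raises(ValueError):
                spectral_embed(sim, mu=mu)


class TestClusterRows:
    def test_two_exact_point_groups(self):
        U = np.array([[1.0, 0]] * 4 + [[0.0, 1]] * 3)
        from gnnsc.spectral_cluster import SpectralEmbedding

        emb = SpectralEmbedding(eigenvalues=np.zeros(2), U=U, row_normalized=True)
        labels = cluster_rows(emb, 2, seed=0)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_mu_one_all_zero_labels(self):
        from gnnsc.spectral_cluster import SpectralEmbedding

        emb = SpectralEmbedding(eigenvalues=np.zeros(1), U=np.ones((5, 1)), row_normalized=True)
        np.testing.assert_array_equal(cluster_rows(emb, 1), 0)

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(6)
        sim = gaussian_similarity(_emb(rng.normal(size=(30, 3))))
        se = spectral_embed(sim, mu=4)
        l1 = cluster_rows(se, 4, seed=11)
        l2 = cluster_rows(se, 4, seed=11)
        np.testing.assert_array_equal(l1, l2)

    def test_node_order_permutation_invariance_up_to_relabel(self):
        emb, labels = _two_clouds(n_per=8, seed=7)
        perm = np.random.default_rng(0).permutation(16)
        emb_p = NodeEmbeddings(
            nodes=tuple(emb.nodes[i] for i in perm), vectors=emb.vectors[perm]
        )
        l1 = cluster_rows(spectral_embed(gaussian_similarity(emb), 2), 2, seed=0)
        l2 = cluster_rows(spectral_embed(gaussian_similarity(emb_p), 2), 2, seed=0)
        assert adjusted_rand_score(l1[perm], l2) == 1.0


class TestPartition:
    def _graph(self, nodes, edges):
        n = len(nodes)
        W = np.zeros((n, n))
        idx = {g: i for i, g in enumerate(nodes)}
        for a, b, w in edges:
            W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
        return GeneGraph(nodes=tuple(nodes), weights=W, init_states=np.zeros((n, 2)))

    def test_bridged_cliques_drop_one_edge(self):
        g = self._graph(
            "abcdef",
            [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
             ("d", "e", 1), ("e", "f", 1), ("d", "f", 1), ("c", "d", 1)],
        )
        ca = partition_graph(g, np.array([0, 0, 0, 1, 1, 1]))
        assert ca.mu == 2
        assert sorted(ca.members(0)) == ["a", "b", "c"]
        assert len(ca.subgraphs[0][1]) == 3 and len(ca.subgraphs[1][1]) == 3  # bridge dropped

    def test_single_cluster_is_whole_graph(self):
        g = self._graph("abc", [("a", "b", 1), ("b", "c", 1)])
        ca = partition_graph(g, np.zeros(3, dtype=int))
        assert ca.members(0) == list(g.nodes)
        assert len(ca.subgraphs[0][1]) == 2

    def test_singleton_cluster_has_no_edges(self):
        g = self._graph("abc", [("a", "b", 1)])
        ca = partition_graph(g, np.array([0, 0, 1]))
        assert ca.members(1) == ["c"] and ca.subgraphs[1][1] == []

    def test_noncontiguous_labels_relabel_canonically(self):
        g = self._graph("abc", [("a", "b", 1)])
        ca = partition_graph(g, np.array([5, 5, 9]))
        assert set(ca.labels.values()) == {0, 1}
        assert ca.labels["a"] == 0 and ca.labels["c"] == 1
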