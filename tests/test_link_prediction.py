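import numpy as np
import pytest

from gnnsc import GNNParams, build_gene_graph
from gnnsc import link_prediction as lp
from gnnsc.gnn import NodeEmbeddings
from gnnsc.graph_build import GeneGraph


def _graph(nodes, weighted_edges, dim=2, seed=0):
    n = len(nodes)
    W = np.zeros((n, n))
    idx = {g: i for i, g in enumerate(nodes)}
    for a, b, w in weighted_edges:
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = w
    states = np.random.default_rng(seed).normal(size=(n, dim))
    return GeneGraph(nodes=tuple(nodes), weights=W, init_states=states)


def _emb(vectors, nodes=None):
    vectors = np.asarray(vectors, float)
    nodes = tuple(nodes or (f"n{i}" for i in range(len(vectors))))
    return NodeEmbeddings(nodes=nodes, vectors=vectors)


class TestNegativeSampling:
    def test_triangle_has_no_legal_negatives(self):
        # in a triangle every node neighbors every other: negative pools are empty
        g = _graph("abc", [("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
        s = lp.build_link_samples(g, gamma=1, seed=0)
        assert len(s.pos) == 3
        assert all(grp == [] for grp in s.neg)

    def test_star_center_contributes_nothing_leaves_pair_up(self):
        g = _graph("cxyz", [("c", "x", 1), ("c", "y", 1), ("c", "z", 1)])
        s = lp.build_link_samples(g, gamma=1, seed=0)
        leaves = {g.index(n) for n in "xyz"}
        for (a, b), grp in zip(s.pos, s.neg):
            assert len(grp) == 1  # only the leaf endpoint has non-neighbors
            (u, v), = grp
            assert {u, v} <= leaves

    def test_negatives_never_reproduce_training_edges(self, study7):
        ds, edges, _ = study7
        g = build_gene_graph(ds, edges)
        s = lp.build_link_samples(g, gamma=3, seed=1)
        adj = g.weights > 0
        for grp in s.neg:
            for u, v in grp:
                assert u != v and not adj[u, v]

    def test_gamma_negatives_per_endpoint(self, study7):
        ds, edges, _ = study7
        g = build_gene_graph(ds, edges)
        s = lp.build_link_samples(g, gamma=4, seed=2)
        assert all(len(grp) == 8 for grp in s.neg)  # sparse graph: never saturated

    def test_same_seed_identical_negatives(self):
        g = _graph("abcdef", [("a", "b", 1), ("c", "d", 1), ("e", "f", 1)])
        s1 = lp.build_link_samples(g, gamma=2, seed=5)
        s2 = lp.build_link_samples(g, gamma=2, seed=5)
        assert s1.neg == s2.neg and s1.pos == s2.pos


class TestSimilarity:
    def test_identical_vectors_score_one(self):
        v = np.array([1.0, 2, -3])
        assert lp.similarity(v, v) == pytest.approx(1.0)
        assert lp.similarity(v, 2.5 * v) == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self):
        assert lp.similarity(np.array([1.0, 0]), np.array([0.0, 1])) == 0.0

    def test_hand_computed_cosine(self):
        s = lp.similarity(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
        assert s == pytest.approx(32 / (np.sqrt(14) * np.sqrt(77)), abs=1e-12)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.normal(size=(2, 4))
            s = lp.similarity(a, b)
            assert s == pytest.approx(lp.similarity(b, a))
            assert -1.0 <= s <= 1.0

    def test_zero_vector_convention_and_shape_error(self):
        assert lp.similarity(np.zeros(3), np.ones(3)) == 0.0
        with pytest.raises(ValueError):
            lp.similarity(np.ones(2), np.ones(3))


class TestLoss:
    def test_single_positive_at_zero_similarity(self):
        emb = _emb([[1, 0], [0, 1]])
        s = lp.LinkSampleSet(nodes=emb.nodes, pos=[(0, 1)], neg=[[]], gamma=1, seed=0)
        assert lp.link_loss(s, emb) == pytest.approx(np.log(2), abs=1e-12)

    def test_positive_plus_negative_at_zero_similarity(self):
        emb = _emb([[1, 0], [0, 1], [1, 0], [0, 1]])
        s = lp.LinkSampleSet(nodes=emb.nodes, pos=[(0, 1)], neg=[[(2, 3)]], gamma=1, seed=0)
        assert lp.link_loss(s, emb) == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_loss_decreases_as_separation_improves(self):
        # positive similarity sweeps up, negative down: loss strictly decreases
        losses = []
        for t in np.linspace(0.0, np.pi / 2, 8):
            pos_pair = np.array([[1.0, 0], [np.cos(np.pi / 2 - t), np.sin(np.pi / 2 - t)]])
            neg_pair = np.array([[1.0, 0], [np.cos(np.pi / 2 + t), np.sin(np.pi / 2 + t)]])
            emb = _emb(np.vstack([pos_pair, neg_pair]))
            s = lp.LinkSampleSet(nodes=emb.nodes, pos=[(0, 1)], neg=[[(2, 3)]], gamma=1, seed=0)
            losses.append(lp.link_loss(s, emb))
        assert all(a > b for a, b in zip(losses, losses[1:]))
        assert all(l > 0 and np.isfinite(l) for l in losses)

    def test_empty_positives_rejected(self):
        emb = _emb([[1, 0], [0, 1]])
        s = lp.LinkSampleSet(nodes=emb.nodes, pos=[], neg=[], gamma=1, seed=0)
        with pytest.raises(ValueError):
            lp.link_loss(s, emb)


class TestMRR:
    def test_perfect_ranking(self):
        assert lp.mean_reciprocal_rank([1, 1, 1]) == 1.0

    def test_hand_computed_value(self):
        assert lp.mean_reciprocal_rank([1, 2, 4]) == pytest.approx(7 / 12, abs=1e-12)

    def test_monotone_decrease_with_rank(self):
        vals = [lp.mean_reciprocal_rank([n]) for n in (1, 2, 5, 50, 500)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_ranks_rejected(self):
        with pytest.raises(ValueError):
            lp.mean_reciprocal_rank([])
        with pytest.raises(ValueError):
            lp.mean_reciprocal_rank([0])

    def test_random_ranker_matches_harmonic_formula(self):
        # E[MRR] over c candidates is H_c / c; check by simulation
        rng = np.random.default_rng(0)
        c = 5
        sims = [1.0 / rng.integers(1, c + 1) for _ in range(20000)]
        expected = lp.expected_random_mrr([c])
        assert np.mean(sims) == pytest.approx(expected, abs=0.01)
        assert expected == pytest.approx((1 + 1 / 2 + 1 / 3 + 1 / 4 + 1 / 5) / 5, abs=1e-12)


class TestTraining:
    def _setup(self):
        g = _graph("abcdefgh", [("a", "b", 1), ("b", "c", 1), ("c", "d", 1),
                                ("e", "f", 1), ("f", "g", 1), ("g", "h", 1)],
                   dim=4, seed=3)
        params = GNNParams.glorot(4, n_layers=2, hidden_dim=4, seed=1)
        samples = lp.build_link_samples(g, gamma=2, seed=2)
        return g, params, samples

    def test_infinite_delta_stops_after_two_epochs(self):
        g, params, samples = self._setup()
        state = lp.train_link_model(g, params, samples, delta=np.inf, max_epochs=50)
        assert state.epoch == 2 and len(state.history) == 2

    def test_fixed_seed_reproduces_history(self):
        g, params, samples = self._setup()
        s1 = lp.train_link_model(g, params, samples, max_epochs=10)
        s2 = lp.train_link_model(g, params, samples, max_epochs=10)
        assert s1.history == s2.history

    def test_best_mrr_is_max_of_history(self):
        g, params, samples = self._setup()
        state = lp.train_link_model(g, params, samples, max_epochs=10)
        assert state.best_mrr == pytest.approx(max(m for _, _, m in state.history))
        assert all(np.isfinite(l) for _, l, _ in state.history)

    def test_max_epochs_without_delta_stop_records_warning(self):
        g, params, samples = self._setup()
        state = lp.train_link_model(g, params, samples, delta=1e-300, max_epochs=3)
        assert state.warnings and "max_epochs" in state.warnings[0]

    def test_invalid_hyperparameters_rejected(self):
        g, params, samples = self._setup()
        for kw in ({"lr": 0.0}, {"delta": 0.0}, {"max_epochs": 0}):
            with pytest.raises(ValueError):
                lp.train_link_model(g, params, samples, **kw)


class TestAugment:
    def test_theta_one_changes_nothing(self):
        g = _graph("abcd", [("a", "b", 1), ("b", "c", 1), ("c", "d", 1)])
        emb = _emb(np.ones((4, 3)), nodes=g.nodes)
        gstar = lp.augment_graph(g, emb, theta=1.0)
        np.testing.assert_array_equal(gstar.weights, g.weights)

    def test_identical_embeddings_add_edge_with_sigmoid_one_weight(self):
        g = _graph("abc", [("a", "b", 1), ("b", "c", 1)])
        emb = _emb(np.ones((3, 2)), nodes=g.nodes)
        gstar = lp.augment_graph(g, emb, theta=0.7)
        w = gstar.weights[g.index("a"), g.index("c")]
        assert w == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-12)  # sigma(1)

    def test_two_hop_scope_never_scores_distant_pairs(self):
        g = _graph("abcd", [("a", "b", 1), ("b", "c", 1), ("c", "d", 1)])
        emb = _emb(np.ones((4, 2)), nodes=g.nodes)
        gstar = lp.augment_graph(g, emb, theta=0.5, candidate_scope="two_hop")
        assert gstar.has_edge("a", "c") and gstar.has_edge("b", "d")
        assert not gstar.has_edge("a", "d")
        gall = lp.augment_graph(g, emb, theta=0.5, candidate_scope="all_pairs")
        assert gall.has_edge("a", "d")

    def test_monotone_in_theta(self, study7):
        ds, edges, _ = study7
        g = build_gene_graph(ds, edges)
        emb = lp.gnn.propagate(g, GNNParams.glorot(g.state_dim, 3, 8, seed=0))
        e_lo = set(map(frozenset, (tuple(p) for p in lp.augment_graph(g, emb, 0.55).edge_pairs())))
        e_hi = set(map(frozenset, (tuple(p) for p in lp.augment_graph(g, emb, 0.72).edge_pairs())))
        assert e_hi <= e_lo

    def test_original_edges_preserved(self, study7):
        ds, edges, _ = study7
        g = build_gene_graph(ds, edges)
        emb = lp.gnn.propagate(g, GNNParams.glorot(g.state_dim, 3, 8, seed=0))
        gstar = lp.augment_graph(g, emb, 0.6)
        mask = g.weights > 0
        np.testing.assert_array_equal(gstar.weights[mask], g.weights[mask])
        assert gstar.n_edges >= g.n_edges
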