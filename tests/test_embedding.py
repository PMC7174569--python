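import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hetmda.embedding import (
    EmbeddingParams,
    WalkCorpus,
    WalkParams,
    generate_walks,
    step_distribution,
    train_skipgram,
    transition_bias,
)
from hetmda.hetnet import HeterogeneousNetwork


def make_net(weights, n_diseases=1):
    weights = np.asarray(weights, dtype=float)
    n = weights.shape[0]
    node_index = [("disease", f"d{i}") for i in range(n_diseases)] + [
        ("microbe", f"m{i}") for i in range(n - n_diseases)
    ]
    return HeterogeneousNetwork(node_index=node_index, weights=weights,
                                n_diseases=n_diseases, self_loops_removed=True)


class TestTransitionBias:
    def test_return_distance_zero(self):
        assert transition_bias(0, p=0.5, q=4.0) == pytest.approx(2.0)

    def test_distance_one_is_unit(self):
        assert transition_bias(1, p=0.123, q=77.0) == pytest.approx(1.0)

    def test_outward_distance_two(self):
        assert transition_bias(2, p=0.5, q=4.0) == pytest.approx(0.25)

    def test_invalid_distance_errors(self):
        with pytest.raises(ValueError):
            transition_bias(3, 1.0, 1.0)


class TestStepDistribution:
    def test_path_graph_symmetric_choice(self):
        # t - u - x chain with unit weights and p = q = 1
        net = make_net([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        probs = step_distribution(net, prev=0, curr=1, params=WalkParams(p=1, q=1))
        np.testing.assert_allclose(probs, [0.5, 0.0, 0.5])

    def test_triangle_biases_hand_normalised(self):
        # after t->u in a unit triangle: back to t has alpha 1/p, x (adjacent
        # to t) has alpha 1
        net = make_net([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        probs = step_distribution(net, prev=0, curr=1, params=WalkParams(p=0.5, q=4.0))
        np.testing.assert_allclose(probs, [2 / 3, 0.0, 1 / 3])

    def test_distance_two_gets_inverse_q(self):
        # square t(0)-u(1)-x(2)-y(3): from u after t, node 2 is NOT adjacent
        # to t, so alpha = 1/q
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 2] = W[2, 3] = W[3, 0] = 1.0
        W = W + W.T
        net = make_net(W)
        probs = step_distribution(net, prev=0, curr=1, params=WalkParams(p=2.0, q=4.0))
        # candidates: t (alpha 1/2), node2 (alpha 1/4); weights unit
        np.testing.assert_allclose(probs, [2 / 3, 0.0, 1 / 3, 0.0])

    def test_first_step_weight_proportional(self):
        net = make_net([[0, 2, 1], [2, 0, 0], [1, 0, 0]])
        probs = step_distribution(net, prev=None, curr=0, params=WalkParams(p=0.5, q=4.0))
        np.testing.assert_allclose(probs, [0.0, 2 / 3, 1 / 3])

    def test_isolated_node_errors(self):
        net = make_net([[0, 0, 0], [0, 0, 1], [0, 1, 0]])
        with pytest.raises(ValueError, match="no neighbours"):
            step_distribution(net, prev=None, curr=0, params=WalkParams())

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5_000), p=st.floats(0.1, 4.0), q=st.floats(0.1, 4.0))
    def test_sums_to_one_and_zero_off_neighbours(self, seed, p, q):
        rng = np.random.default_rng(seed)
        n = 6
        W = np.triu((rng.random((n, n)) < 0.6) * rng.random((n, n)), k=1)
        W = W + W.T
        if not (W.sum(axis=1) > 0).all():
            W[0, 1] = W[1, 0] = 1.0
            W[np.arange(n - 1), np.arange(1, n)] = 1.0
            W = np.triu(W, 1) + np.triu(W, 1).T
        net = make_net(W)
        params = WalkParams(p=p, q=q)
        for prev, curr in [(None, 0), (0, 1), (2, 3)]:
            if prev is not None and net.weights[prev, curr] == 0:
                continue
            probs = step_distribution(net, prev, curr, params)
            assert abs(probs.sum() - 1.0) < 1e-12
            assert (probs[net.weights[curr] == 0] == 0).all()


class TestGenerateWalks:
    def test_two_node_network_alternates(self):
        net = make_net([[0, 1], [1, 0]])
        corpus = generate_walks(net, WalkParams(walk_length=10, walks_per_node=2, seed=1))
        assert len(corpus.walks) == 4
        for walk in corpus.walks:
            assert len(walk) == 10
            assert all(a != b for a, b in zip(walk[:-1], walk[1:]))

    def test_walks_start_from_every_node_each_pass(self, small_net):
        params = WalkParams(walk_length=5, walks_per_node=3, seed=2)
        corpus = generate_walks(small_net, params)
        starts = [w[0] for w in corpus.walks]
        assert len(corpus.walks) == small_net.n_nodes * 3
        counts = np.bincount(starts, minlength=small_net.n_nodes)
        np.testing.assert_array_equal(counts, np.full(small_net.n_nodes, 3))

    def test_consecutive_nodes_share_positive_edge(self, small_net, fast_walk_params):
        corpus = generate_walks(small_net, fast_walk_params)
        for walk in corpus.walks:
            for a, b in zip(walk[:-1], walk[1:]):
                assert small_net.weights[a, b] > 0

    def test_fixed_seed_reproducible(self, small_net, fast_walk_params):
        c1 = generate_walks(small_net, fast_walk_params)
        c2 = generate_walks(small_net, fast_walk_params)
        assert [w.tolist() for w in c1.walks] == [w.tolist() for w in c2.walks]

    def test_dead_end_truncates_without_error(self):
        # node 2 is isolated: its walks stop immediately
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 1.0
        corpus = generate_walks(make_net(W), WalkParams(walk_length=5, walks_per_node=1, seed=0))
        lengths = {w[0]: len(w) for w in corpus.walks}
        assert lengths[2] == 1
        assert lengths[0] == 5 and lengths[1] == 5

    def test_first_step_frequencies_match_distribution(self, small_net):
        params = WalkParams(p=0.5, q=4.0, walk_length=2, walks_per_node=700, seed=3)
        corpus = generate_walks(small_net, params)
        analytic = {
            u: step_distribution(small_net, None, u, params) for u in range(small_net.n_nodes)
        }
        counts = np.zeros((small_net.n_nodes, small_net.n_nodes))
        for walk in corpus.walks:
            if len(walk) > 1:
                counts[walk[0], walk[1]] += 1
        for u in range(small_net.n_nodes):
            n = counts[u].sum()
            expected = analytic[u] * n
            se = np.sqrt(n * analytic[u] * (1 - analytic[u]))
            mask = se > 0
            assert (np.abs(counts[u] - expected)[mask] <= 3.5 * se[mask]).all()

    def test_text_export_one_walk_per_line(self, small_net, fast_walk_params, tmp_path):
        corpus = generate_walks(small_net, fast_walk_params)
        path = tmp_path / "walks.txt"
        corpus.write_text(path)
        lines = path.read_text().splitlines()
        assert len(lines) == len(corpus.walks)
        assert lines[0].split(" ")[0] in corpus.node_labels


class TestSkipgram:
    def test_requested_dimension_honoured(self, small_net, fast_walk_params):
        corpus = generate_walks(small_net, fast_walk_params)
        emb = train_skipgram(corpus, EmbeddingParams(dimension=128, context_size=4,
                                                     epochs=1, seed=0))
        assert emb.vectors.shape == (small_net.n_nodes, 128)
        assert np.isfinite(emb.vectors).all()

    def test_deterministic_given_seed(self, small_net, fast_walk_params, fast_emb_params):
        corpus = generate_walks(small_net, fast_walk_params)
        e1 = train_skipgram(corpus, fast_emb_params)
        e2 = train_skipgram(corpus, fast_emb_params)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_co_occurring_nodes_closer_than_strangers(self):
        # nodes 0,1 always share a walk; 2,3 likewise; pairs never mix
        walks = []
        for _ in range(40):
            walks += [np.array([0, 1, 0, 1]), np.array([1, 0, 1, 0]),
                      np.array([2, 3, 2, 3]), np.array([3, 2, 3, 2])]
        corpus = WalkCorpus(walks=walks, node_labels=["a", "b", "c", "d"])
        emb = train_skipgram(corpus, EmbeddingParams(dimension=8, context_size=3,
                                                     epochs=10, seed=4))
        def cos(x, y):
            return np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y))
        v = emb.vectors
        assert cos(v[0], v[1]) > cos(v[0], v[2])
        assert cos(v[0], v[1]) > cos(v[0], v[3])
        assert cos(v[2], v[3]) > cos(v[2], v[0])

    def test_missing_node_errors(self):
        corpus = WalkCorpus(walks=[np.array([0, 1])], node_labels=["a", "b", "c"])
        with pytest.raises(ValueError, match="absent"):
            train_skipgram(corpus, EmbeddingParams(dimension=4, epochs=1))

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError, match="empty"):
            train_skipgram(WalkCorpus(walks=[], node_labels=["a"]),
                           EmbeddingParams(dimension=4))

    def test_word2vec_text_round_trip(self, small_net, fast_walk_params,
                                      fast_emb_params, tmp_path):
        corpus = generate_walks(small_net, fast_walk_params)
        emb = train_skipgram(corpus, fast_emb_params)
        path = tmp_path / "emb.txt"
        emb.write_word2vec(path)
        header = path.read_text().splitlines()[0]
        assert header == f"{small_net.n_nodes} {fast_emb_params.dimension}"
        from hetmda.embedding import EmbeddingTable
        back = EmbeddingTable.read_word2vec(path)
        assert back.ids == emb.ids
        np.testing.assert_array_equal(back.vectors, emb.vectors)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(p=0.0), dict(q=-1.0), dict(walk_length=1), dict(walks_per_node=0)],
    )
    def test_invalid_walk_params(self, kwargs):
        with pytest.raises(ValueError):
            WalkParams(**kwargs)

    @pytest.mark.parametrize(
        "kwargs", [dict(dimension=0), dict(context_size=0), dict(epochs=0)]
    )
    def test_invalid_embedding_params(self, kwargs):
        with pytest.raises(ValueError):
            EmbeddingParams(**kwargs)
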