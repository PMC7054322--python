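import numpy as np
import pytest
from scipy import stats

from subcomp import line_embedding as le
from conftest import random_toy_graph, toy_graph


def brute_first_order(graph, emb):
    """Independent per-edge accumulation of the first-order objective."""
    total = 0.0
    for i, j, w in graph.edges():
        x = float(np.dot(emb.vector(i), emb.vector(j)))
        total += -w * np.log(1.0 / (1.0 + np.exp(-x)))
    return total


def brute_second_order(graph, emb):
    """Double loop over directed edges with an explicit softmax."""
    nodes = emb.node_ids.tolist()
    total = 0.0
    directed = []
    for i, j, w in graph.edges():
        directed += [(i, j, w), (j, i, w)]
    for i, j, w in directed:
        scores = np.array([np.dot(emb.context_vector(k), emb.vector(i))
                           for k in nodes])
        p = np.exp(scores - scores.max())
        p /= p.sum()
        total += -w * np.log(p[nodes.index(j)])
    return total


def random_embedding(rng, n, d, with_context=True):
    return le.EmbeddingMatrix(
        np.arange(n), rng.normal(0, 0.5, (n, d)),
        context=rng.normal(0, 0.5, (n, d)) if with_context else None)


class TestFirstOrder:
    def test_sigmoid_values(self):
        e = np.zeros(3)
        assert le.first_order_prob(e, e) == 0.5
        u = np.array([1.0, 0.0])
        assert le.first_order_prob(u, u) == pytest.approx(1 / (1 + np.exp(-1)))

    def test_symmetry(self, rng):
        for _ in range(10):
            a, b = rng.normal(size=(2, 8))
            assert le.first_order_prob(a, b) == le.first_order_prob(b, a)

    def test_dim_mismatch(self):
        with pytest.raises(ValueError):
            le.first_order_prob(np.zeros(3), np.zeros(4))

    def test_objective_closed_form_zero_embedding(self):
        g = toy_graph(2, [(0, 1, 2.0)])
        emb = le.EmbeddingMatrix(np.arange(2), np.zeros((2, 4)))
        assert le.first_order_objective(g, emb) == pytest.approx(2 * np.log(2))

    def test_objective_all_zero_equals_W_log2(self, rng):
        g = random_toy_graph(rng, 8)
        emb = le.EmbeddingMatrix(np.arange(8), np.zeros((8, 4)))
        assert le.first_order_objective(g, emb) == pytest.approx(g.W * np.log(2))

    def test_objective_matches_brute_force(self, rng):
        g = random_toy_graph(rng, 10)
        emb = random_embedding(rng, 10, 6)
        assert le.first_order_objective(g, emb) == pytest.approx(
            brute_first_order(g, emb), abs=1e-10)


class TestSecondOrder:
    def test_uniform_softmax_when_contexts_identical(self, rng):
        n = 7
        ctx = np.tile(rng.normal(size=5), (n, 1))
        emb = le.EmbeddingMatrix(np.arange(n), rng.normal(size=(n, 5)), context=ctx)
        for j in range(n):
            assert le.second_order_prob(emb, 0, j) == pytest.approx(1 / n)

    def test_rows_sum_to_one(self, rng):
        emb = random_embedding(rng, 9, 4)
        for i in range(9):
            total = sum(le.second_order_prob(emb, i, j) for j in range(9))
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_three_node_instance_matches_direct_formula(self):
        vec = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, -0.5]])
        ctx = np.array([[0.2, 0.1], [-0.3, 0.4], [0.0, 1.0]])
        emb = le.EmbeddingMatrix(np.arange(3), vec, context=ctx)
        scores = ctx @ vec[0]
        expected = np.exp(scores[1]) / np.exp(scores).sum()
        assert le.second_order_prob(emb, 0, 1) == pytest.approx(expected, abs=1e-12)

    def test_empty_node_set_rejected(self, rng):
        emb = random_embedding(rng, 3, 2)
        with pytest.raises(ValueError):
            le.second_order_prob(emb, 0, 1, node_set=[])

    def test_objective_uniform_closed_form(self, rng):
        g = random_toy_graph(rng, 6)
        emb = le.EmbeddingMatrix(np.arange(6), np.zeros((6, 3)),
                                 context=np.zeros((6, 3)))
        assert le.second_order_objective(g, emb) == pytest.approx(
            2 * g.W * np.log(6))

    def test_single_edge_definition(self):
        g = toy_graph(2, [(0, 1, 3.0)])
        rng = np.random.default_rng(0)
        emb = random_embedding(rng, 2, 4)
        expected = -3.0 * (np.log(le.second_order_prob(emb, 0, 1))
                           + np.log(le.second_order_prob(emb, 1, 0)))
        assert le.second_order_objective(g, emb) == pytest.approx(expected)

    def test_objective_matches_brute_force(self, rng):
        g = random_toy_graph(rng, 8)
        emb = random_embedding(rng, 8, 5)
        assert le.second_order_objective(g, emb) == pytest.approx(
            brute_second_order(g, emb), abs=1e-10)


class TestSampler:
    def test_single_edge_always_drawn(self):
        g = toy_graph(2, [(0, 1, 5.0)])
        s = le.build_sampler(g, seed=0)
        i, j = s.sample_edges(100)
        assert np.all(i == 0) and np.all(j == 1)

    def test_edge_frequencies_weighted(self):
        g = toy_graph(3, [(0, 1, 1.0), (0, 2, 3.0)])
        s = le.build_sampler(g, seed=1)
        n = 100_000
        _, j = s.sample_edges(n)
        frac_heavy = np.mean(j == 2)
        sigma = np.sqrt(0.75 * 0.25 / n)
        assert abs(frac_heavy - 0.75) < 3 * sigma

    def test_equal_weights_uniform_chisquare(self):
        edges = [(i, j, 1.0) for i in range(5) for j in range(i + 1, 5)]
        g = toy_graph(5, edges)
        s = le.build_sampler(g, seed=2)
        n = 50_000
        i, j = s.sample_edges(n)
        keys = i * 10 + j
        counts = np.array([np.sum(keys == a * 10 + b) for a, b, _ in edges])
        chi2 = ((counts - n / len(edges)) ** 2 / (n / len(edges))).sum()
        assert stats.chi2.sf(chi2, len(edges) - 1) > 0.01

    def test_negative_draw_distribution_follows_degree_power(self):
        g = toy_graph(3, [(0, 1, 1.0), (0, 2, 7.0)])
        s = le.build_sampler(g, seed=3)
        n = 100_000
        nodes = s.sample_nodes(n)
        p = g.degree ** 0.75
        p /= p.sum()
        for node in range(3):
            frac = np.mean(nodes == node)
            sigma = np.sqrt(p[node] * (1 - p[node]) / n)
            assert abs(frac - p[node]) < 4 * sigma

    def test_reproducible_per_seed(self, planted):
        _, _, graph, _ = planted
        a = le.build_sampler(graph, seed=7).sample_edges(50)
        b = le.build_sampler(graph, seed=7).sample_edges(50)
        np.testing.assert_array_equal(a, b)

    def test_empty_graph_rejected(self):
        g = toy_graph(2, [(0, 1, 1.0)])
        g.edge_w = np.empty(0)
        g.edge_i = g.edge_j = np.empty(0, dtype=np.int64)
        with pytest.raises(ValueError):
            le.build_sampler(g)


def numeric_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for c in range(len(x)):
        xp, xm = x.copy(), x.copy()
        xp[c] += eps
        xm[c] -= eps
        g[c] = (f(xp) - f(xm)) / (2 * eps)
    return g


class TestSgdUpdates:
    @pytest.mark.parametrize("label", ["pos", "neg"])
    def test_first_order_gradient_matches_finite_difference(self, rng, label):
        for _ in range(20):
            u_i, u_j = rng.normal(0, 1, (2, 6))
            lr = 0.1

            def loss_i(x):
                s = 1.0 / (1.0 + np.exp(-(x @ u_j)))
                return -np.log(s if label == "pos" else 1 - s)

            new_i, _ = le.sgd_update_first(u_i, u_j, label, lr)
            step = (new_i - u_i) / lr
            expected = -numeric_gradient(loss_i, u_i)
            np.testing.assert_allclose(step, expected, rtol=1e-5, atol=1e-8)

    def test_second_order_gradient_matches_finite_difference(self, rng):
        for _ in range(20):
            u_i = rng.normal(0, 1, 5)
            ctx_j = rng.normal(0, 1, 5)
            negs = [rng.normal(0, 1, 5) for _ in range(3)]
            lr = 0.05

            def loss_i(x):
                tot = -np.log(1 / (1 + np.exp(-(x @ ctx_j))))
                for c in negs:
                    tot += -np.log(1 / (1 + np.exp(x @ c)))
                return tot

            new_i, _, _ = le.sgd_update_second(u_i, ctx_j, negs, lr)
            np.testing.assert_allclose((new_i - u_i) / lr,
                                       -numeric_gradient(loss_i, u_i),
                                       rtol=1e-5, atol=1e-8)

    def test_saturated_positive_pair_barely_moves(self):
        u = np.full(4, 10.0)
        new_i, new_j = le.sgd_update_first(u, u, "pos", lr=1.0)
        assert np.max(np.abs(new_i - u)) < 1e-8

    def test_update_scales_linearly_with_lr(self, rng):
        u_i, u_j = rng.normal(0, 1, (2, 4))
        a, _ = le.sgd_update_first(u_i, u_j, "pos", lr=0.01)
        b, _ = le.sgd_update_first(u_i, u_j, "pos", lr=0.02)
        np.testing.assert_allclose(b - u_i, 2 * (a - u_i), rtol=1e-12)

    def test_positive_second_order_raises_score(self, rng):
        u_i = rng.normal(0, 0.1, 4)
        ctx_j = rng.normal(0, 0.1, 4)
        new_i, new_j, _ = le.sgd_update_second(u_i, ctx_j, [], lr=0.1)
        assert new_i @ new_j > u_i @ ctx_j

    def test_unsampled_vectors_untouched(self, rng):
        u_i = rng.normal(size=3)
        ctx_j = rng.normal(size=3)
        negs = [rng.normal(size=3)]
        keep = negs[0].copy()
        le.sgd_update_second(u_i, ctx_j, negs, lr=0.1)
        np.testing.assert_array_equal(negs[0], keep)  # inputs not mutated


@pytest.fixture(scope="module")
def fixture30():
    from subcomp import synthetic_data as sd
    cfg = sd.SimConfig(n_chroms=3, bins_per_chrom=10, K=3, seed=2)
    _, graph, labels = sd.simulate_hic(cfg)
    return graph, labels


class TestTraining:

    def test_training_reduces_exact_objectives(self, fixture30):
        graph, _ = fixture30
        cfg = le.TrainingConfig(dim=16, samples=0.2, alpha=0.5, seed=2)
        init = le.initial_embedding(graph, cfg)
        emb = le.train(graph, cfg)
        assert le.first_order_objective(graph, emb) < \
            le.first_order_objective(graph, init)
        assert le.second_order_objective(graph, emb) < \
            le.second_order_objective(graph, init)

    def test_alpha_one_only_second_order(self, fixture30):
        graph, _ = fixture30
        cfg = le.TrainingConfig(dim=8, samples=0.01, alpha=1.0, seed=3)
        emb = le.train(graph, cfg)
        n_first, n_second = emb.update_counts
        assert n_first == 0 and n_second == cfg.n_draws

    def test_deterministic_per_seed_single_worker(self, fixture30):
        graph, _ = fixture30
        cfg = le.TrainingConfig(dim=8, samples=0.05, seed=5, workers=1)
        a = le.train(graph, cfg)
        b = le.train(graph, cfg)
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_separate_mode_concatenates_normalized_orders(self, fixture30):
        graph, _ = fixture30
        cfg = le.TrainingConfig(dim=8, samples=0.05, mode="separate", seed=4)
        emb = le.train(graph, cfg)
        assert emb.dim == 16
        norms = np.linalg.norm(emb.vectors[:, :8], axis=1)
        np.testing.assert_allclose(norms, 1.0, rtol=1e-9)

    def test_within_block_cosine_exceeds_between(self, fixture30):
        graph, labels = fixture30
        cfg = le.TrainingConfig(dim=16, samples=0.3, seed=6)
        emb = le.train(graph, cfg)
        v = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        lab = labels[emb.node_ids]
        cos = v @ v.T
        same = lab[:, None] == lab[None, :]
        off = ~np.eye(len(lab), dtype=bool)
        assert cos[same & off].mean() > cos[~same].mean()

    def test_too_few_nodes_rejected(self):
        g = toy_graph(2, [(0, 1, 1.0)])
        g.degree = np.array([1.0, 0.0])
        with pytest.raises(ValueError):
            le.train(g, le.TrainingConfig(dim=4, samples=0.001))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            le.TrainingConfig(alpha=1.5)
        with pytest.raises(ValueError):
            le.TrainingConfig(negative=0)
        with pytest.raises(ValueError):
            le.TrainingConfig(samples=-1)

    def test_embedding_tsv_roundtrip(self, fixture30, tmp_path):
        graph, _ = fixture30
        cfg = le.TrainingConfig(dim=8, samples=0.01, seed=1)
        emb = le.train(graph, cfg)
        path = tmp_path / "emb.tsv"
        emb.save(str(path))
        back = le.EmbeddingMatrix.load(str(path))
        np.testing.assert_array_equal(back.node_ids, emb.node_ids)
        np.testing.assert_array_equal(back.vectors, emb.vectors)
        assert back.mode == "joint"
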