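import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from conftest import ppi, protein
from hetppi.hetnet import HeteroNetwork, NodeRef, TypedEdge
from hetppi.line_embed import (
    AliasSampler,
    EmbeddingTable,
    LineConfig,
    build_edge_sampler,
    build_noise_sampler,
    first_order_proximity,
    intra_view_features,
    negative_sampling_grads,
    negative_sampling_loss,
    second_order_conditional,
    train_line,
)
from oracles import exact_softmax_second_order


def table_of(vertex, context=None):
    n, d = np.asarray(vertex).shape
    nodes = tuple(protein(i) for i in range(n))
    vertex = np.asarray(vertex, dtype=float)
    context = np.asarray(context, dtype=float) if context is not None else np.zeros_like(vertex)
    return EmbeddingTable(nodes, vertex, context)


class TestFirstOrderProximity:
    def test_zero_vectors_give_half(self):
        assert first_order_proximity(np.zeros(4), np.zeros(4)) == 0.5

    def test_log3_dot_gives_three_quarters(self):
        u = np.array([math.log(3.0), 0.0])
        v = np.array([1.0, 5.0])
        assert first_order_proximity(u, v) == pytest.approx(0.75)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            u, v = rng.normal(size=(2, 8))
            assert first_order_proximity(u, v) == pytest.approx(first_order_proximity(v, u))

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            first_order_proximity(np.zeros(3), np.zeros(4))


class TestSecondOrderConditional:
    def test_zero_contexts_give_uniform(self):
        t = table_of(np.ones((4, 3)), np.zeros((4, 3)))
        for i in range(4):
            assert second_order_conditional(protein(i), protein(0), t) == pytest.approx(0.25)

    def test_normalizes_over_all_nodes(self):
        rng = np.random.default_rng(1)
        t = table_of(rng.normal(size=(7, 5)), rng.normal(size=(7, 5)))
        for j in range(3):
            total = sum(
                second_order_conditional(protein(i), protein(j), t) for i in range(7)
            )
            assert total == pytest.approx(1.0)

    def test_matches_hand_computed_softmax(self):
        V = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        C = np.array([[0.5, 0.5], [2.0, 0.0], [0.0, -1.0]])
        logits = C @ V[0]
        expected = np.exp(logits[1]) / np.exp(logits).sum()
        assert second_order_conditional(protein(1), protein(0), table_of(V, C)) == pytest.approx(expected)

    def test_missing_node_is_error(self):
        t = table_of(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            second_order_conditional(protein(5), protein(0), t)


class TestSamplers:
    def test_single_edge_drawn_with_certainty(self):
        net = HeteroNetwork(edges=[ppi(1, 2)])
        sampler = build_edge_sampler(net, seed=0)
        assert all(e == ppi(1, 2) for e in sampler.draw(size=20))

    def test_star_hub_drawn_half_the_time(self):
        hub = protein(0)
        net = HeteroNetwork(edges=[ppi(0, i) for i in range(1, 5)])
        sampler = build_noise_sampler(net, exponent=1.0, seed=0)
        draws = sampler.draw(size=10_000)
        frac = sum(n == hub for n in draws) / 10_000
        sigma = math.sqrt(0.5 * 0.5 / 10_000)
        assert abs(frac - 0.5) < 3 * sigma

    def test_exponent_zero_is_uniform(self):
        net = HeteroNetwork(edges=[ppi(0, i) for i in range(1, 5)])
        sampler = build_noise_sampler(net, exponent=0.0, seed=1)
        draws = sampler.draw(size=10_000)
        counts = [sum(n == node for n in draws) for node in sampler.nodes]
        assert sps.chisquare(counts).pvalue > 0.01

    def test_empty_network_is_error(self):
        with pytest.raises(ValueError):
            build_edge_sampler(HeteroNetwork(nodes=[protein(1)]))

    def test_alias_sampler_matches_target_distribution(self):
        probs = np.array([0.5, 0.25, 0.125, 0.125])
        sampler = AliasSampler(probs)
        rng = np.random.default_rng(3)
        draws = sampler.draw(rng, size=40_000)
        freq = np.bincount(draws, minlength=4) / 40_000
        assert np.allclose(freq, probs, atol=0.01)


class TestGradients:
    def test_analytic_matches_central_differences(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=6) * 0.3
        pos = rng.normal(size=6) * 0.3
        negs = rng.normal(size=(4, 6)) * 0.3
        gu, gp, gn = negative_sampling_grads(u, pos, negs)
        eps = 1e-6

        def num_grad(f, x):
            g = np.zeros_like(x)
            for idx in np.ndindex(x.shape):
                d = np.zeros_like(x)
                d[idx] = eps
                g[idx] = (f(x + d) - f(x - d)) / (2 * eps)
            return g

        gu_num = num_grad(lambda x: negative_sampling_loss(x, pos, negs), u)
        gp_num = num_grad(lambda x: negative_sampling_loss(u, x, negs), pos)
        gn_num = num_grad(lambda x: negative_sampling_loss(u, pos, x), negs)
        for a, b in ((gu, gu_num), (gp, gp_num), (gn, gn_num)):
            assert np.max(np.abs(a - b)) / max(np.max(np.abs(b)), 1e-12) < 1e-5


def two_cliques(size=6):
    edges = []
    for base in (0, size):
        for i, j in itertools.combinations(range(base, base + size), 2):
            edges.append(ppi(i, j))
    return HeteroNetwork(edges=edges)


class TestTrainLine:
    def test_same_seed_gives_bitwise_identical_tables(self):
        net = two_cliques(4)
        cfg = LineConfig(dim_per_order=8, total_samples=5_000, seed=11)
        f1, s1 = train_line(net, cfg)
        f2, s2 = train_line(net, cfg)
        assert np.array_equal(f1.vertex, f2.vertex)
        assert np.array_equal(s1.vertex, s2.vertex)
        assert np.array_equal(s1.context, s2.context)

    def test_cliques_separate_under_first_order(self):
        net = two_cliques(6)
        first, _ = train_line(net, LineConfig(dim_per_order=8, total_samples=40_000, seed=2))
        intra, inter = [], []
        for a, b in itertools.combinations(sorted(net.nodes), 2):
            p = first_order_proximity(first.vector(a), first.vector(b))
            (intra if (int(a.id[1:]) < 6) == (int(b.id[1:]) < 6) else inter).append(p)
        assert np.mean(intra) > np.mean(inter)

    def test_shared_neighbors_imply_similar_second_order_vectors(self):
        # a and b share all five neighbors without a mutual edge; ten other
        # nodes form an unrelated random graph sharing no neighbours with a
        rng = np.random.default_rng(0)
        edges = [ppi(i, j) for i in (0, 1) for j in range(2, 7)]
        for i, j in itertools.combinations(range(7, 17), 2):
            if rng.random() < 0.35:
                edges.append(ppi(i, j))
        net = HeteroNetwork(edges=edges)
        _, second = train_line(net, LineConfig(dim_per_order=16, total_samples=100_000, seed=4))

        def cos(x, y):
            return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))

        a, b = second.vector(protein(0)), second.vector(protein(1))
        sim_ab = cos(a, b)
        others = [cos(a, second.vector(protein(i))) for i in range(7, 17)]
        assert sim_ab > max(others)

    def test_norms_stay_finite_across_random_graphs(self):
        rng = np.random.default_rng(8)
        for trial in range(20):
            n = int(rng.integers(8, 25))
            edges = [
                ppi(i, j)
                for i, j in itertools.combinations(range(n), 2)
                if rng.random() < 0.3
            ]
            if not edges:
                continue
            cfg = LineConfig(dim_per_order=6, total_samples=3_000, seed=trial)
            first, second = train_line(HeteroNetwork(edges=edges), cfg)
            for t in (first, second):
                assert np.isfinite(t.vertex).all() and np.isfinite(t.context).all()

    def test_sgd_ranks_pairs_like_exact_softmax_oracle(self):
        # 6-node graph: two triangles joined by one edge
        edges = [ppi(0, 1), ppi(1, 2), ppi(0, 2), ppi(3, 4), ppi(4, 5), ppi(3, 5), ppi(2, 3)]
        net = HeteroNetwork(edges=edges)
        _, second = train_line(net, LineConfig(dim_per_order=4, total_samples=120_000, seed=6))
        adjacency = {i: set() for i in range(6)}
        for e in edges:
            i, j = int(e.u.id[1:]), int(e.v.id[1:])
            adjacency[i].add(j)
            adjacency[j].add(i)
        V, C = exact_softmax_second_order(adjacency, 6, 4, seed=6)
        sgd_scores, oracle_scores = [], []
        for i, j in itertools.permutations(range(6), 2):
            sgd_scores.append(second_order_conditional(protein(j), protein(i), second))
            logits = C @ V[i]
            p = np.exp(logits - logits.max())
            oracle_scores.append(p[j] / p.sum())
        rho = sps.spearmanr(sgd_scores, oracle_scores).statistic
        assert rho > 0.8

    def test_community_separability_on_planted_partition(self):
        rng = np.random.default_rng(12)
        block = [i // 50 for i in range(100)]
        edges = []
        for i, j in itertools.combinations(range(100), 2):
            p = 0.2 if block[i] == block[j] else 0.01
            if rng.random() < p:
                edges.append(ppi(i, j))
        net = HeteroNetwork(edges=edges)
        first, _ = train_line(net, LineConfig(dim_per_order=16, seed=3))
        from sklearn.linear_model import LogisticRegression

        nodes = sorted(net.nodes)
        X = np.stack([first.vector(n) for n in nodes])
        y = np.array([block[int(n.id[1:])] for n in nodes])
        acc = LogisticRegression(max_iter=2000).fit(X, y).score(X, y)
        assert acc >= 0.95

    def test_no_edges_is_error(self):
        with pytest.raises(ValueError):
            train_line(HeteroNetwork(nodes=[protein(0)]))


class TestIntraViewFeatures:
    def test_concatenation_layout_and_isolated_node(self):
        net = HeteroNetwork(nodes=[protein(9)], edges=[ppi(0, 1), ppi(1, 2)])
        first, second = train_line(net, LineConfig(dim_per_order=4, total_samples=2_000, seed=0))
        feats = intra_view_features(first, second, sorted(net.nodes))
        vec = feats[protein(0)]
        assert vec.shape == (8,)
        assert np.array_equal(vec[:4], first.vector(protein(0)))
        assert np.array_equal(vec[4:], second.vector(protein(0)))
        # isolated node was never sampled: finite initialization returned
        iso = feats[protein(9)]
        assert np.isfinite(iso).all()
        assert np.array_equal(iso[:4], first.vector(protein(9)))

    def test_missing_node_is_error(self):
        net = HeteroNetwork(edges=[ppi(0, 1)])
        first, second = train_line(net, LineConfig(dim_per_order=2, total_samples=500, seed=0))
        with pytest.raises(KeyError):
            intra_view_features(first, second, [protein(7)])
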