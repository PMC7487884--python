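"""Embedding objectives, gradients, samplers, and both trainers."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from linedti.errors import ConfigError, DimensionError, ModeError
from linedti.line import (
    LineConfig,
    LineModelState,
    build_alias_table,
    exact_train_small,
    first_order_gradient,
    first_order_joint,
    first_order_objective,
    negative_sampling_objective,
    read_embedding,
    second_order_conditional,
    second_order_gradient,
    second_order_objective,
    train_line,
    write_embedding,
)

from conftest import protein_graph


def random_state(g, dim, seed, order="second"):
    rng = np.random.default_rng(seed)
    nodes = tuple(g.node_names())
    U = rng.normal(scale=0.6, size=(len(nodes), dim))
    C = rng.normal(scale=0.6, size=(len(nodes), dim)) if order == "second" else None
    return LineModelState(nodes, U, C, LineConfig(dim=dim, order=order), order)


def zero_state(g, dim, order="second"):
    nodes = tuple(g.node_names())
    U = np.zeros((len(nodes), dim))
    C = np.zeros((len(nodes), dim)) if order == "second" else None
    return LineModelState(nodes, U, C, LineConfig(dim=dim, order=order), order)


class TestFirstOrderJoint:
    def test_zero_dot_product_is_half(self):
        assert first_order_joint(np.ones(4), np.zeros(4)) == 0.5
        assert first_order_joint(np.zeros(3), np.zeros(3)) == 0.5

    def test_log3_dot_product(self):
        u = np.array([math.log(3.0), 0.0])
        v = np.array([1.0, 5.0])
        assert first_order_joint(u, v) == pytest.approx(0.75, abs=1e-12)

    @given(
        hnp.arrays(np.float64, 6, elements=st.floats(-3, 3)),
        hnp.arrays(np.float64, 6, elements=st.floats(-3, 3)),
    )
    def test_symmetric_and_in_unit_interval(self, u, v):
        p = first_order_joint(u, v)
        assert p == first_order_joint(v, u)
        assert 0.0 < p < 1.0

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            first_order_joint(np.zeros(3), np.zeros(4))


class TestSecondOrderConditional:
    def test_identical_contexts_give_uniform(self, triangle):
        state = zero_state(triangle, 4)
        state.context_vectors[:] = 1.0
        for j in triangle.node_names():
            assert second_order_conditional(state, "a", j) == pytest.approx(1 / 3)

    def test_two_class_softmax_closed_form(self):
        g = protein_graph([("a", "b")])
        state = zero_state(g, 2)
        state.vertex_vectors[0, 0] = 1.0
        state.context_vectors[:, 0] = [math.log(3.0), 0.0]
        assert second_order_conditional(state, "a", "a") == pytest.approx(0.75, abs=1e-12)
        assert second_order_conditional(state, "a", "b") == pytest.approx(0.25, abs=1e-12)

    def test_normalisation(self, two_cliques):
        g, names = two_cliques
        state = random_state(g, 8, seed=3)
        for i in names[:4]:
            total = sum(second_order_conditional(state, i, j) for j in names)
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_first_order_state_rejected(self, triangle):
        state = zero_state(triangle, 4, order="first")
        with pytest.raises(ModeError):
            second_order_conditional(state, "a", "b")


class TestObjectives:
    def test_zero_embedding_first_order_value(self, two_cliques):
        g, _ = two_cliques
        state = zero_state(g, 8, order="first")
        assert first_order_objective(state, g) == pytest.approx(
            g.num_edges * math.log(2.0), rel=1e-12
        )

    def test_saturated_edge_loss_vanishes(self):
        g = protein_graph([("a", "b")])
        state = zero_state(g, 2, order="first")
        state.vertex_vectors[:] = [[20.0, 0.0], [20.0, 0.0]]
        assert first_order_objective(state, g) < 1e-8

    def test_single_edge_log3_gives_log_4_3(self):
        g = protein_graph([("a", "b")])
        state = zero_state(g, 2, order="first")
        state.vertex_vectors[0] = [math.log(3.0), 0.0]
        state.vertex_vectors[1] = [1.0, 0.0]
        assert first_order_objective(state, g) == pytest.approx(math.log(4 / 3), rel=1e-12)

    def test_zero_embedding_second_order_value(self, two_cliques):
        g, names = two_cliques
        state = zero_state(g, 8)
        expected = 2 * g.num_edges * math.log(len(names))
        assert second_order_objective(state, g) == pytest.approx(expected, rel=1e-12)

    def test_second_order_decreases_under_small_step_gd(self):
        g = protein_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("a", "f")])
        state = random_state(g, 4, seed=0)
        losses = [second_order_objective(state, g)]
        for _ in range(20):
            gu, gc = second_order_gradient(state, g)
            state.vertex_vectors -= 0.01 * gu
            state.context_vectors -= 0.01 * gc
            losses.append(second_order_objective(state, g))
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_second_order_gradient_matches_finite_differences(self, seed):
        g = protein_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("a", "c")])
        state = random_state(g, 3, seed=seed)
        gu, gc = second_order_gradient(state, g)
        eps = 1e-6
        rng = np.random.default_rng(seed)
        for arr, grad in ((state.vertex_vectors, gu), (state.context_vectors, gc)):
            for _ in range(6):
                i = rng.integers(arr.shape[0])
                d = rng.integers(arr.shape[1])
                arr[i, d] += eps
                up = second_order_objective(state, g)
                arr[i, d] -= 2 * eps
                down = second_order_objective(state, g)
                arr[i, d] += eps
                numeric = (up - down) / (2 * eps)
                assert abs(numeric - grad[i, d]) <= 1e-5 * max(1.0, abs(numeric))

    def test_first_order_gradient_matches_finite_differences(self):
        g = protein_graph([("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")])
        state = random_state(g, 3, seed=4, order="first")
        grad = first_order_gradient(state, g)
        eps = 1e-6
        for i in range(4):
            for d in range(3):
                state.vertex_vectors[i, d] += eps
                up = first_order_objective(state, g)
                state.vertex_vectors[i, d] -= 2 * eps
                down = first_order_objective(state, g)
                state.vertex_vectors[i, d] += eps
                numeric = (up - down) / (2 * eps)
                assert abs(numeric - grad[i, d]) <= 1e-5 * max(1.0, abs(numeric))


class TestAliasTable:
    @pytest.mark.parametrize(
        "weights,expected",
        [([1.0, 1.0], [0.5, 0.5]), ([1.0, 3.0], [0.25, 0.75])],
    )
    def test_empirical_frequencies(self, weights, expected):
        table = build_alias_table(weights, seed=0)
        n = 100_000
        draws = table.sample(n)
        for idx, p in enumerate(expected):
            freq = np.mean(draws == idx)
            sigma = math.sqrt(p * (1 - p) / n)
            assert abs(freq - p) < 3 * sigma

    def test_single_weight_always_zero(self):
        table = build_alias_table([2.0], seed=1)
        assert np.all(table.sample(100) == 0)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ConfigError):
            build_alias_table([1.0, 0.0])


class TestExactTrainer:
    def test_loss_history_non_increasing(self, two_cliques):
        g, _ = two_cliques
        for order in ("first", "second"):
            state = exact_train_small(g, LineConfig(dim=8, order=order, seed=0), iters=50)
            h = state.loss_history
            assert all(b <= a for a, b in zip(h, h[1:]))
            assert h[-1] <= h[0]

    def test_triangle_first_order_beats_zero_embedding(self, triangle):
        state = exact_train_small(triangle, LineConfig(dim=4, order="first", seed=0))
        assert state.loss_history[-1] < 3 * math.log(2.0)

    def test_size_limit_directs_to_scalable_trainer(self):
        g = protein_graph([(f"n{i}", f"n{i+1}") for i in range(210)])
        with pytest.raises(ConfigError, match="train_line"):
            exact_train_small(g)

    def test_concat_mode_concatenates_halves(self, triangle):
        state = exact_train_small(triangle, LineConfig(dim=8, order="concat", seed=0), iters=20)
        assert state.vertex_vectors.shape == (3, 8)
        assert state.order == "concat"


class TestScalableTrainer:
    def test_same_seed_bitwise_identical(self, two_cliques):
        g, _ = two_cliques
        cfg = LineConfig(dim=8, order="concat", seed=42, total_samples=20_000)
        a = train_line(g, cfg)
        b = train_line(g, cfg)
        assert np.array_equal(a.vertex_vectors, b.vertex_vectors)

    def test_different_seeds_differ(self, two_cliques):
        g, _ = two_cliques
        a = train_line(g, LineConfig(dim=8, seed=1, total_samples=5_000))
        b = train_line(g, LineConfig(dim=8, seed=2, total_samples=5_000))
        assert not np.array_equal(a.vertex_vectors, b.vertex_vectors)

    def test_isolated_nodes_keep_initialisation(self):
        g = protein_graph([("a", "b")])
        g.add_node("iso", "protein")
        cfg = LineConfig(dim=4, order="first", seed=0, total_samples=2_000)
        state = train_line(g, cfg)
        v = state.vector("iso")
        assert np.all(np.abs(v) <= 0.5 / 4)

    def test_empty_graph_rejected(self):
        from linedti.network import HeteroGraph

        with pytest.raises(ConfigError):
            train_line(HeteroGraph(), LineConfig())

    def test_odd_dim_concat_rejected(self):
        with pytest.raises(ConfigError):
            LineConfig(dim=7, order="concat")


def test_negative_sampling_surrogate_ranks_like_exact_objective(two_cliques):
    """The NS surrogate must order candidate states like the exact softmax loss.

    States are drawn with random magnitudes as well as random directions,
    spanning near-initialisation to strongly-fitted scales.
    """
    g, _ = two_cliques
    exact_vals, surrogate_vals = [], []
    for seed in range(10):
        state = random_state(g, 6, seed=seed)
        scale = 0.1 + 0.15 * seed  # magnitudes spanning 0.1 .. 1.45
        state.vertex_vectors *= scale
        state.context_vectors *= scale
        exact_vals.append(second_order_objective(state, g))
        surrogate_vals.append(negative_sampling_objective(state, g, k_negative=5))
    from scipy.stats import spearmanr

    rho = spearmanr(exact_vals, surrogate_vals).statistic
    assert rho > 0.9


def test_structural_twins_embed_together():
    """Nodes with identical neighbourhoods get the most similar second-order vectors."""
    edges = [("t1", h) for h in ("h1", "h2", "h3")]
    edges += [("t2", h) for h in ("h1", "h2", "h3")]
    edges += [("x", "h1"), ("y", "h3"), ("x", "y")]
    g = protein_graph(edges)
    state = exact_train_small(g, LineConfig(dim=6, order="second", seed=0), iters=400)

    def cos(a, b):
        va, vb = state.vector(a), state.vector(b)
        return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

    twin_sim = cos("t1", "t2")
    others = [cos("t1", n) for n in ("x", "y", "h1", "h2", "h3")]
    assert twin_sim > max(others)


def test_embedding_text_round_trip(tmp_path, triangle):
    state = exact_train_small(triangle, LineConfig(dim=4, order="first", seed=0), iters=5)
    path = tmp_path / "vectors.txt"
    write_embedding(state, path, types={n: "protein" for n in triangle.node_names()})
    loaded = read_embedding(path)
    assert set(loaded) == set(triangle.node_names())
    for name in loaded:
        assert loaded[name] == pytest.approx(state.vector(name), abs=1e-5)
    assert (tmp_path / "vectors.txt.types.json").exists()
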