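"""Graph-learning solver: objective values, oracle equivalence, feasibility,
network construction, and serialization."""

import numpy as np
import pytest
from conftest import random_dissimilarity, solve_oracle

from motionsync import (
    GraphLearningConfig,
    build_all_networks,
    build_network,
    learn_graph,
    objective,
)
from motionsync.errors import ConvergenceError, InvalidInputError
from motionsync.graph_learning import (
    load_network_graphml,
    load_network_json,
    save_network_graphml,
    save_network_json,
    threshold_edges,
)

TIGHT = GraphLearningConfig(z_scaling="none", tolerance=1e-13, max_iterations=500_000)


class TestObjective:
    def test_all_zero_weights_hit_barrier(self):
        Z = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert objective(np.zeros((2, 2)), Z, GraphLearningConfig()) == np.inf

    def test_two_vertex_worked_value(self):
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        Z = np.array([[0.0, 4.0], [4.0, 0.0]])
        cfg = GraphLearningConfig(barrier_weight=1.0, frobenius_weight=0.0)
        assert objective(W, Z, cfg) == pytest.approx(4.0)

    def test_scaling_shifts_barrier_by_n_log_c(self):
        rng = np.random.default_rng(0)
        n = 5
        W = rng.uniform(0.1, 1.0, (n, n))
        W = 0.5 * (W + W.T)
        np.fill_diagonal(W, 0.0)
        Z = random_dissimilarity(rng, n)
        cfg = GraphLearningConfig(barrier_weight=1.3, frobenius_weight=0.0)
        c = 2.7
        got = objective(c * W, Z, cfg)
        expected = c * 0.5 * np.sum(W * Z) + (
            objective(W, Z, cfg) - 0.5 * np.sum(W * Z)
        ) - cfg.barrier_weight * n * np.log(c)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            objective(np.zeros((2, 2)), np.zeros((3, 3)), GraphLearningConfig())


class TestSolver:
    def test_matches_convex_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(3, 7))
            Z = random_dissimilarity(rng, n)
            W = learn_graph(Z, TIGHT)
            Wo = solve_oracle(Z, TIGHT)
            fo = objective(Wo, Z, TIGHT)
            fp = objective(W, Z, TIGHT)
            assert abs(fp - fo) <= 1e-6 * abs(fo)

    def test_feasibility_invariants(self):
        rng = np.random.default_rng(1)
        for n in (3, 6, 12):
            W = learn_graph(random_dissimilarity(rng, n))
            np.testing.assert_allclose(W, W.T, atol=1e-12)
            assert (W >= 0).all()
            np.testing.assert_array_equal(np.diag(W), 0.0)
            assert (W.sum(axis=1) > 0).all()

    def test_most_similar_pair_gets_largest_weight(self):
        Z = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        W = learn_graph(Z, TIGHT)
        off = [(W[0, 1], (0, 1)), (W[0, 2], (0, 2)), (W[1, 2], (1, 2))]
        assert max(off)[1] == (0, 1)
        assert W[0, 1] > W[0, 2] and W[0, 1] > W[1, 2]

    def test_uniform_dissimilarity_gives_uniform_weights(self):
        n = 5
        Z = np.full((n, n), 3.0)
        np.fill_diagonal(Z, 0.0)
        W = learn_graph(Z, TIGHT)
        iu, ju = np.triu_indices(n, 1)
        w = W[iu, ju]
        assert w.max() - w.min() < 1e-6
        fo = objective(solve_oracle(Z, TIGHT), Z, TIGHT)
        assert objective(W, Z, TIGHT) == pytest.approx(fo, rel=1e-6)

    def test_monotone_response_to_dissimilarity(self):
        # raising one Z entry never raises the learned weight on that pair
        rng = np.random.default_rng(3)
        Z = random_dissimilarity(rng, 4)
        base = learn_graph(Z, TIGHT)[0, 1]
        for bump in (1.0, 3.0, 8.0):
            Z2 = Z.copy()
            Z2[0, 1] = Z2[1, 0] = Z[0, 1] + bump
            w = learn_graph(Z2, TIGHT)[0, 1]
            assert w <= base + 1e-8
            base = w

    def test_deterministic(self):
        Z = random_dissimilarity(np.random.default_rng(4), 6)
        W1 = learn_graph(Z)
        W2 = learn_graph(Z)
        np.testing.assert_array_equal(W1, W2)

    def test_nonconvergence_reports_last_change(self):
        Z = random_dissimilarity(np.random.default_rng(5), 8)
        with pytest.raises(ConvergenceError, match="relative change"):
            learn_graph(Z, GraphLearningConfig(tolerance=1e-16, max_iterations=5))


class TestNetworkConstruction:
    def test_coupled_pair_becomes_edge(self, small_cohort):
        cohort, truth = small_cohort
        for p in cohort.participants:
            if p.group != "stroke":
                continue
            net = build_network(
                cohort.movement_series(p.id, 0), participant=p.id, movement=0
            )
            assert (0, 1) in net.edges  # planted stroke coupling on movement 0

    def test_null_channel_has_no_edges(self):
        from motionsync import SyntheticConfig, generate_cohort

        cfg = SyntheticConfig(
            n_stroke_L=1,
            n_stroke_R=0,
            n_ctrl=0,
            n_movements=1,
            n_angles=6,
            couplings={"stroke": [((0, 1), 0), ((2, 3), 0)]},
            null_channels={"stroke": [5]},
            duration_range=(80, 120),
            m_max=200,
            seed=11,
        )
        cohort, _ = generate_cohort(cfg)
        cohort.resample_all()
        net = build_network(
            cohort.movement_series("stroke_1", 0), participant="stroke_1"
        )
        assert all(5 not in pair for pair in net.edges)

    def test_same_input_same_network(self, small_cohort):
        cohort, _ = small_cohort
        series = cohort.movement_series(cohort.participants[0].id, 1)
        a = build_network(series)
        b = build_network(series)
        np.testing.assert_array_equal(a.weights, b.weights)
        assert a.edges == b.edges

    def test_build_all_counts_and_order(self, small_cohort):
        cohort, _ = small_cohort
        nets = build_all_networks(cohort)
        assert len(nets) == cohort.n_participants * cohort.n_movements
        keys = [(n.participant, n.movement) for n in nets]
        expected = [
            (p.id, m)
            for p in cohort.participants
            for m in range(cohort.n_movements)
        ]
        assert keys == expected  # participant-major, movement-minor
        assert all(n.n_vertices == cohort.n_angles for n in nets)

    def test_threshold_edges_relative_to_max(self):
        W = np.array([[0, 1.0, 0.004], [1.0, 0, 0.2], [0.004, 0.2, 0]])
        assert threshold_edges(W, 0.05) == {(0, 1), (1, 2)}
        assert threshold_edges(np.zeros((3, 3)), 0.05) == set()


class TestSerialization:
    def test_graphml_round_trip(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        net = build_all_networks(cohort)[0]
        path = tmp_path / "net.graphml"
        save_network_graphml(net, path, angles=cohort.angles)
        back = load_network_graphml(path, n_vertices=net.n_vertices)
        assert back.participant == net.participant
        assert back.movement == net.movement
        assert back.edges == net.edges
        for i, j in net.edges:
            assert back.weights[i, j] == net.weights[i, j]  # lossless floats

    def test_json_round_trip(self, small_cohort, tmp_path):
        cohort, _ = small_cohort
        net = build_all_networks(cohort)[3]
        path = tmp_path / "net.json"
        save_network_json(net, path)
        back = load_network_json(path)
        assert back.edges == net.edges
        for i, j in net.edges:
            assert back.weights[i, j] == net.weights[i, j]
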