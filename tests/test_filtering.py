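"""Union edge set and the filter algebra, checked against brute force."""

import numpy as np
import pytest

from motionsync import (
    FilterSpec,
    build_union_set,
    edge_support,
    filter_edges,
    group_exclusive_edges,
    most_prevalent_edges,
)
from motionsync.cohort import Cohort, JointAngle, ParticipantSide
from motionsync.errors import ConfigError
from motionsync.graph_learning import MotionNetwork

ALL_GROUPS = frozenset(["strokeL", "strokeR", "ctrlL", "ctrlR"])


def toy_world(rng, n_participants=6, n_movements=3, n_angles=5, p_edge=0.4):
    """Random networks with known edges over a metadata-only cohort."""
    groups = ["strokeL", "strokeR", "ctrlL", "ctrlR"]
    participants = []
    for i in range(n_participants):
        tok = groups[i % 4]
        participants.append(
            ParticipantSide(
                f"p{i}",
                "stroke" if tok.startswith("stroke") else "control",
                tok[-1],
            )
        )
    angles = [JointAngle(i, f"a{i}", "shoulder", i) for i in range(n_angles)]
    cohort = Cohort(angles, [f"M{m+1}" for m in range(n_movements)], participants)
    nets = []
    for p in participants:
        for m in range(n_movements):
            W = np.zeros((n_angles, n_angles))
            for i in range(n_angles):
                for j in range(i + 1, n_angles):
                    if rng.random() < p_edge:
                        W[i, j] = W[j, i] = rng.uniform(0.5, 1.0)
            nets.append(
                MotionNetwork(p.id, m, W, edge_threshold_rel=0.0)
            )
    return cohort, nets


class TestUnionSet:
    def test_record_count_is_sum_of_edge_counts(self):
        rng = np.random.default_rng(0)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        assert len(u) == sum(len(n.edges) for n in nets)
        assert len(u.network_keys) == len(nets)

    def test_single_network_matches_its_edge_list(self):
        rng = np.random.default_rng(1)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets[:1], cohort)
        assert {r.pair for r in u.records} == nets[0].edges

    def test_empty_collection(self):
        rng = np.random.default_rng(2)
        cohort, _ = toy_world(rng)
        u = build_union_set([], cohort)
        assert len(u) == 0 and not u.distinct_pairs()

    def test_unknown_participant_rejected(self):
        rng = np.random.default_rng(3)
        cohort, nets = toy_world(rng)
        rogue = MotionNetwork("ghost", 0, nets[0].weights, edge_threshold_rel=0.0)
        with pytest.raises(ConfigError, match="ghost"):
            build_union_set([rogue], cohort)


class TestFilters:
    def test_full_domain_filter_is_identity(self):
        rng = np.random.default_rng(4)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        spec = FilterSpec(ALL_GROUPS, frozenset(range(3)))
        assert len(filter_edges(u, spec)) == len(u)

    def test_restriction_matches_brute_force(self):
        rng = np.random.default_rng(5)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        spec = FilterSpec(frozenset(["strokeL"]), frozenset([1]))
        sub = filter_edges(u, spec)
        tok = {p.id: p.group_side for p in cohort.participants}
        expected = [
            (n.participant, n.movement, pair)
            for n in nets
            for pair in sorted(n.edges)
            if tok[n.participant] == "strokeL" and n.movement == 1
        ]
        got = [(r.participant, r.movement, r.pair) for r in sub.records]
        assert sorted(got) == sorted(expected)

    def test_disjoint_domains_partition_the_union(self):
        rng = np.random.default_rng(6)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        total = 0
        for tok in ALL_GROUPS:
            for m in range(3):
                total += len(
                    filter_edges(u, FilterSpec(frozenset([tok]), frozenset([m])))
                )
        assert total == len(u)

    def test_individual_selection(self):
        rng = np.random.default_rng(7)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        spec = FilterSpec(ALL_GROUPS, frozenset(range(3)), individuals=frozenset(["p0"]))
        sub = filter_edges(u, spec)
        assert {r.participant for r in sub.records} <= {"p0"}

    def test_unknown_movement_rejected(self):
        rng = np.random.default_rng(8)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        with pytest.raises(ConfigError):
            filter_edges(u, FilterSpec(ALL_GROUPS, frozenset([99])))


class TestSupport:
    def test_support_matches_brute_force_on_random_toys(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            cohort, nets = toy_world(rng, n_participants=4, n_movements=2, n_angles=4)
            u = build_union_set(nets, cohort)
            tok = {p.id: p.group_side for p in cohort.participants}
            spec = FilterSpec(
                frozenset(["strokeL", "ctrlR"]), frozenset([rng.integers(0, 2)])
            )
            for pair in [(0, 1), (1, 3), (2, 3)]:
                expected = sum(
                    1
                    for n in nets
                    if tok[n.participant] in spec.groups
                    and n.movement in spec.movements
                    and pair in n.edges
                )
                assert edge_support(u, spec, pair) == expected

    def test_support_bounded_by_domain_size(self):
        rng = np.random.default_rng(9)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        spec = FilterSpec(ALL_GROUPS, frozenset(range(3)))
        n_dom = len(filter_edges(u, spec).network_keys)
        for pair in u.distinct_pairs():
            assert 0 <= edge_support(u, spec, pair) <= n_dom

    def test_absent_pair_scores_zero(self):
        rng = np.random.default_rng(10)
        cohort, nets = toy_world(rng, p_edge=0.0)
        u = build_union_set(nets, cohort)
        assert edge_support(u, FilterSpec(ALL_GROUPS, frozenset([0])), (0, 1)) == 0


class TestRanking:
    def test_topk_matches_sorted_brute_force(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cohort, nets = toy_world(rng)
            u = build_union_set(nets, cohort)
            spec = FilterSpec(ALL_GROUPS, frozenset(range(3)), mode="topk", k=4)
            ranked = most_prevalent_edges(u, spec, 4)
            brute = {}
            for pair in filter_edges(u, spec).distinct_pairs():
                brute[pair] = edge_support(u, spec, pair)
            expected = sorted(brute.items(), key=lambda kv: (-kv[1], kv[0]))[:4]
            assert ranked == expected

    def test_k_one_returns_argmax_head(self):
        rng = np.random.default_rng(11)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        spec = FilterSpec(ALL_GROUPS, frozenset(range(3)))
        (pair, support), = most_prevalent_edges(u, spec, 1)
        assert support == max(
            edge_support(u, spec, p) for p in u.distinct_pairs()
        )

    def test_tie_break_is_lexicographic(self):
        angles = [JointAngle(i, f"a{i}", "shoulder", i) for i in range(4)]
        cohort = Cohort(angles, ["M1"], [ParticipantSide("p0", "stroke", "L")])
        W = np.zeros((4, 4))
        W[0, 3] = W[3, 0] = 1.0
        W[1, 2] = W[2, 1] = 1.0
        u = build_union_set([MotionNetwork("p0", 0, W, edge_threshold_rel=0.0)], cohort)
        spec = FilterSpec(frozenset(["strokeL"]), frozenset([0]))
        assert most_prevalent_edges(u, spec, 2) == [((0, 3), 1), ((1, 2), 1)]


class TestGroupComparison:
    def test_exclusive_and_shared_sets(self):
        angles = [JointAngle(i, f"a{i}", "shoulder", i) for i in range(4)]
        cohort = Cohort(
            angles,
            ["M1"],
            [ParticipantSide("s", "stroke", "L"), ParticipantSide("c", "control", "L")],
        )
        Ws = np.zeros((4, 4))
        Ws[0, 1] = Ws[1, 0] = 1.0  # x
        Ws[1, 2] = Ws[2, 1] = 1.0  # y
        Wc = np.zeros((4, 4))
        Wc[1, 2] = Wc[2, 1] = 1.0  # y
        Wc[2, 3] = Wc[3, 2] = 1.0  # z
        u = build_union_set(
            [
                MotionNetwork("s", 0, Ws, edge_threshold_rel=0.0),
                MotionNetwork("c", 0, Wc, edge_threshold_rel=0.0),
            ],
            cohort,
        )
        only_a, only_b, shared = group_exclusive_edges(
            u,
            FilterSpec(frozenset(["strokeL"]), frozenset([0])),
            FilterSpec(frozenset(["ctrlL"]), frozenset([0])),
        )
        assert (only_a, only_b, shared) == ({(0, 1)}, {(2, 3)}, {(1, 2)})

    def test_identical_domains_have_no_exclusives(self):
        rng = np.random.default_rng(12)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        spec = FilterSpec(ALL_GROUPS, frozenset(range(3)))
        only_a, only_b, shared = group_exclusive_edges(u, spec, spec)
        assert only_a == only_b == set()
        assert shared == u.distinct_pairs()

    def test_partition_property(self):
        rng = np.random.default_rng(13)
        cohort, nets = toy_world(rng)
        u = build_union_set(nets, cohort)
        sa = FilterSpec(frozenset(["strokeL", "strokeR"]), frozenset(range(3)))
        sb = FilterSpec(frozenset(["ctrlL", "ctrlR"]), frozenset(range(3)))
        only_a, only_b, shared = group_exclusive_edges(u, sa, sb)
        assert not (only_a & only_b) and not (only_a & shared) and not (only_b & shared)
        assert only_a | only_b | shared == (
            filter_edges(u, sa).distinct_pairs() | filter_edges(u, sb).distinct_pairs()
        )


class TestSpecValidation:
    def test_bad_specs_rejected(self):
        with pytest.raises(ConfigError):
            FilterSpec(frozenset(), frozenset([0]))
        with pytest.raises(ConfigError):
            FilterSpec(frozenset(["martians"]), frozenset([0]))
        with pytest.raises(ConfigError):
            FilterSpec(frozenset(["strokeL"]), frozenset())
        with pytest.raises(ConfigError):
            FilterSpec(frozenset(["strokeL"]), frozenset([0]), mode="topk", k=0)
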