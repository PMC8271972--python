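"""Union edge structure and set-theoretic edge filtering.

All learned networks share the same vertex set (the joint angles), so
their edge sets can be pooled into one provenance-tagged multiset E_U:
each record remembers which (participant-side, movement) network
contributed it.  Analyses are phrased as filters over E_U: restrict to
group/side tokens, movements and optionally individuals, then either keep
everything, rank pairs by support (in how many in-domain networks the pair
is an edge), or compare two domains for exclusive/shared pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import json
from pathlib import Path

from .cohort import GROUP_SIDE_TOKENS, Cohort
from .errors import ConfigError, InvalidInputError
from .graph_learning import MotionNetwork

Pair = tuple[int, int]


@dataclass(frozen=True)
class EdgeRecord:
    """One edge of one network, with provenance."""

    pair: Pair
    participant: str
    movement: int
    weight: float

    def __post_init__(self) -> None:
        i, j = self.pair
        if i == j:
            raise InvalidInputError("edge endpoints must be distinct")
        if self.weight <= 0:
            raise InvalidInputError("post-threshold edges carry positive weight")


@dataclass
class UnionEdgeSet:
    """Multiset of edge records plus the set of contributing networks.

    ``network_keys`` also lists networks that contributed zero edges, so
    support counts can be related to the number of in-domain networks.
    ``group_side`` maps participant id -> token in {strokeL, strokeR,
    ctrlL, ctrlR}.
    """

    records: list[EdgeRecord] = field(default_factory=list)
    network_keys: set[tuple[str, int]] = field(default_factory=set)
    group_side: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def distinct_pairs(self) -> set[Pair]:
        return {r.pair for r in self.records}


@dataclass(frozen=True)
class FilterSpec:
    """Declarative filter over the union edge set.

    mode is one of "all", "topk" (with k >= 1), "differences",
    "intersection"; the last two are evaluated against a second spec by
    :func:`group_exclusive_edges`.
    """

    groups: frozenset[str]
    movements: frozenset[int]
    individuals: frozenset[str] | None = None
    mode: str = "all"
    k: int | None = None

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigError("filter needs at least one group/side token")
        unknown = set(self.groups) - set(GROUP_SIDE_TOKENS)
        if unknown:
            raise ConfigError(f"unknown group tokens {sorted(unknown)}")
        if not self.movements:
            raise ConfigError("filter needs at least one movement")
        if self.mode not in ("all", "topk", "differences", "intersection"):
            raise ConfigError(f"unknown filter mode {self.mode!r}")
        if self.mode == "topk" and (self.k is None or self.k < 1):
            raise ConfigError("topk mode requires k >= 1")


def build_union_set(networks, cohort: Cohort) -> UnionEdgeSet:
    """Pool all edges of all networks, tagged with provenance."""
    group_side = {p.id: p.group_side for p in cohort.participants}
    out = UnionEdgeSet(group_side=group_side)
    for net in networks:
        if net.participant not in group_side:
            raise ConfigError(
                f"network references unknown participant {net.participant!r}"
            )
        out.network_keys.add((net.participant, net.movement))
        for i, j in sorted(net.edges):
            out.records.append(
                EdgeRecord(
                    pair=(i, j),
                    participant=net.participant,
                    movement=net.movement,
                    weight=float(net.weights[i, j]),
                )
            )
    return out


def _in_domain(u: UnionEdgeSet, spec: FilterSpec, participant: str, movement: int) -> bool:
    if movement not in spec.movements:
        return False
    if u.group_side.get(participant) not in spec.groups:
        return False
    if spec.individuals is not None and participant not in spec.individuals:
        return False
    return True


def _check_movements(u: UnionEdgeSet, spec: FilterSpec) -> None:
    known = {m for _, m in u.network_keys}
    if known:
        bad = {m for m in spec.movements if m < 0 or m > max(known)}
        if bad:
            raise ConfigError(f"unknown movement ids {sorted(bad)}")


def filter_edges(u: UnionEdgeSet, spec: FilterSpec) -> UnionEdgeSet:
    """Subset of records (and network keys) inside the filter domain."""
    _check_movements(u, spec)
    records = [r for r in u.records if _in_domain(u, spec, r.participant, r.movement)]
    keys = {k for k in u.network_keys if _in_domain(u, spec, *k)}
    return UnionEdgeSet(records=records, network_keys=keys, group_side=dict(u.group_side))


def edge_support(u: UnionEdgeSet, spec: FilterSpec, pair: Pair) -> int:
    """Number of distinct in-domain networks containing ``pair`` as an edge."""
    pair = tuple(sorted(pair))
    nets = {
        (r.participant, r.movement)
        for r in u.records
        if r.pair == pair and _in_domain(u, spec, r.participant, r.movement)
    }
    return len(nets)


def most_prevalent_edges(u: UnionEdgeSet, spec: FilterSpec, k: int) -> list[tuple[Pair, int]]:
    """Distinct pairs ranked by support (descending).

    Ties are broken lexicographically on (smaller id, larger id) so the
    ranking is deterministic.  Support counts one unit per (participant,
    movement) network, even when several movements are in the domain.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    sub = filter_edges(u, replace(spec, mode="all", k=None))
    support = Counter({pair: 0 for pair in sub.distinct_pairs()})
    for pair in support:
        support[pair] = len(
            {(r.participant, r.movement) for r in sub.records if r.pair == pair}
        )
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def group_exclusive_edges(
    u: UnionEdgeSet, spec_a: FilterSpec, spec_b: FilterSpec
) -> tuple[set[Pair], set[Pair], set[Pair]]:
    """Partition pairs of two domains by presence pattern.

    Presence means support >= 1 anywhere in the domain; magnitudes are not
    compared.  Returns (only_a, only_b, shared).
    """
    for spec in (spec_a, spec_b):
        if spec.mode != "all":
            raise ConfigError("group comparison expects mode='all' specs")
    pairs_a = filter_edges(u, spec_a).distinct_pairs()
    pairs_b = filter_edges(u, spec_b).distinct_pairs()
    return pairs_a - pairs_b, pairs_b - pairs_a, pairs_a & pairs_b


def export_edges_json(
    u: UnionEdgeSet, spec: FilterSpec, cohort: Cohort, path, k: int | None = None
) -> dict:
    """Write a filtered edge report (pairs, names, supports, contributors)."""
    sub = filter_edges(u, replace(spec, mode="all", k=None))
    if spec.mode == "topk":
        ranked = most_prevalent_edges(u, spec, k or spec.k or 1)
        pairs = [p for p, _ in ranked]
    else:
        pairs = sorted(sub.distinct_pairs())
    names = {a.id: a.name for a in cohort.angles}
    payload = {
        "n_networks": len(sub.network_keys),
        "edges": [
            {
                "pair": list(pair),
                "angles": [names[pair[0]], names[pair[1]]],
                "support": edge_support(u, spec, pair),
                "participants": sorted(
                    {r.participant for r in sub.records if r.pair == pair}
                ),
            }
            for pair in pairs
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
    return payload
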