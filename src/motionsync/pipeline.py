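"""Glue between cohorts, network collections, and the 2-D views.

These helpers are what the CLI calls; they are plain library functions so
scripted analyses can use them directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .autoencoder import train_autoencoder
from .cohort import Cohort
from .descriptors import mds_project, network_features, pca_project
from .errors import ConfigError, InvalidInputError
from .filtering import FilterSpec, UnionEdgeSet, filter_edges, group_exclusive_edges
from .graph_learning import MotionNetwork, load_network_json, save_network_json
from .render import ArcDiagramSpec

PROJECTION_METHODS = ("net-pca", "curve-pca", "ae-mds")


def network_filename(participant: str, movement: int) -> str:
    return f"{participant}_M{movement + 1:02d}.json"


def save_networks(networks, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for net in networks:
        save_network_json(net, out / network_filename(net.participant, net.movement))


def load_networks(in_dir) -> list[MotionNetwork]:
    paths = sorted(Path(in_dir).glob("*.json"))
    if not paths:
        raise InvalidInputError(f"no network JSON files under {in_dir}")
    return [load_network_json(p) for p in paths]


def _normalize_curve(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def projection_coords(
    cohort: Cohort,
    movement: int,
    method: str,
    networks: list[MotionNetwork] | None = None,
    seed: int = 0,
    ae_epochs: int = 60,
) -> pd.DataFrame:
    """Per-participant 2-D coordinates for one movement.

    net-pca: PCA of the 4*N_A network-centrality feature vector.
    curve-pca: PCA of the per-series z-scored motion curves, concatenated
    over angles.
    ae-mds: classical MDS of concatenated autoencoder embeddings; the
    autoencoder is trained on all traces of the movement (with reversed
    copies) using ``seed``.
    """
    if method not in PROJECTION_METHODS:
        raise ConfigError(f"unknown projection method {method!r}")
    pids = [p.id for p in cohort.participants]
    if method == "net-pca":
        if networks is None:
            raise ConfigError("net-pca needs the learned networks")
        by_pid = {
            net.participant: net for net in networks if net.movement == movement
        }
        missing = [pid for pid in pids if pid not in by_pid]
        if missing:
            raise ConfigError(f"no network for participants {missing} on this movement")
        vectors = [network_features(by_pid[pid]) for pid in pids]
        xy = pca_project(vectors)
    elif method == "curve-pca":
        vectors = [
            np.concatenate(
                [
                    _normalize_curve(ts.values)
                    for ts in cohort.movement_series(pid, movement)
                ]
            )
            for pid in pids
        ]
        xy = pca_project(vectors)
    else:
        all_series = [
            ts for pid in pids for ts in cohort.movement_series(pid, movement)
        ]
        model = train_autoencoder(all_series, seed=seed, epochs=ae_epochs)
        vectors = [
            np.concatenate(
                [model.encode(ts) for ts in cohort.movement_series(pid, movement)]
            )
            for pid in pids
        ]
        xy = mds_project(vectors)
    rows = []
    for pid, (x, y) in zip(pids, xy):
        p = cohort.participant(pid)
        rows.append(
            {
                "participant": pid,
                "x": float(x),
                "y": float(y),
                "group": p.group,
                "side": p.side,
                "fma_total": p.fma_total,
            }
        )
    return pd.DataFrame(rows)


def difference_arc_spec(
    u: UnionEdgeSet, cohort: Cohort, movements, stroke_sides=("L", "R"), ctrl_sides=("L", "R")
) -> ArcDiagramSpec:
    """Arc-view spec contrasting stroke vs control edge sets.

    Pairs present only in stroke networks are classed "stroke-only", only
    in control networks "control-only", in both "shared"; arc thickness
    carries the pooled support.  Angles are laid out by display rank.
    """
    movements = frozenset(movements)
    spec_s = FilterSpec(frozenset("stroke" + s for s in stroke_sides), movements)
    spec_c = FilterSpec(frozenset("ctrl" + s for s in ctrl_sides), movements)
    only_s, only_c, shared = group_exclusive_edges(u, spec_s, spec_c)
    order = sorted(cohort.angles, key=lambda a: a.display_rank)
    pos = {a.id: rank for rank, a in enumerate(order)}
    labels = [a.name for a in order]

    both = FilterSpec(spec_s.groups | spec_c.groups, movements)
    support = {
        pair: len(
            {
                (r.participant, r.movement)
                for r in filter_edges(u, both).records
                if r.pair == pair
            }
        )
        for pair in only_s | only_c | shared
    }
    arcs = []
    for pair_set, cls in ((only_s, "stroke-only"), (only_c, "control-only"), (shared, "shared")):
        for pair in sorted(pair_set):
            arcs.append(((pos[pair[0]], pos[pair[1]]), support[pair], cls))
    return ArcDiagramSpec(labels=labels, arcs=arcs)
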