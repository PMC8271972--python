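"""Smoothness-based graph learning with a log-degree barrier.

One weighted undirected network is learned per (participant-side, movement)
recording by minimizing, over symmetric non-negative zero-diagonal
adjacency matrices W,

    F(W) = 1/2 sum_ij W_ij Z_ij  -  alpha * sum_i log(sum_j W_ij)
           + gamma * ||W||_F^2

where Z is the pairwise channel dissimilarity.  The Dirichlet-energy term
puts weight on similar channel pairs, the log barrier on vertex degrees
forbids isolated vertices, and the Frobenius term controls density.  The
problem is convex; we solve it with a primal-dual splitting scheme on the
upper-triangular weight vector, where the linear "degree operator" S maps
pair weights to vertex degrees.

Writing w for the n(n-1)/2 upper-triangular weights and z likewise for Z,
the vector form is

    min_{w >= 0}  2 z.w  -  alpha 1'log(S w)  +  2 gamma ||w||^2.

The scheme below is the Condat-Vu primal-dual iteration: a proximal
gradient step on the smooth 2*gamma||w||^2 part and the proximable
linear-plus-positivity part, and a dual step on the barrier composed with
S.  The barrier's proximal map has the closed form
prox_{t}(x) = (x + sqrt(x^2 + 4 t alpha)) / 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import numpy as np

from .cohort import Cohort, JointAngle
from .dissimilarity import PenaltyWeights, dissimilarity_matrix
from .errors import ConvergenceError, InvalidInputError


@dataclass(frozen=True)
class GraphLearningConfig:
    """Solver and thresholding parameters.

    barrier_weight (alpha) must be positive: it is what guarantees that
    every vertex keeps a positive degree.  frobenius_weight (gamma)
    trades sparsity against weight spread; at the optimum a pair (i, j)
    carries weight only if 2 Z_ij < alpha (1/d_i + 1/d_j), and for
    vertices holding one strong partner d ~ sqrt(alpha / 2 gamma), so the
    default gamma = 0.125 places the connection cutoff at Z ~ 0.7 - on
    the correlation-distance scale used by the pipeline (Z in [0, 4+]),
    that means only genuinely co-varying pairs (rho > ~0.65) connect.
    ``z_scaling="mean-normalize"`` optionally divides the off-diagonal
    dissimilarities by their mean before solving, for inputs that are not
    already O(1).

    An entry W_ij counts as an edge iff W_ij > edge_threshold_rel *
    max(W).  The log barrier leaves every vertex - including motionless
    channels that synchronize with nothing - a small positive degree
    spread thinly over many partners; the default threshold of 0.05
    sits above that barrier floor (~1% of the maximum weight) and well
    below genuine edge weights (>~30%).
    """

    barrier_weight: float = 1.0
    frobenius_weight: float = 0.125
    z_scaling: str = "none"
    max_iterations: int = 5000
    tolerance: float = 1e-6
    edge_threshold_rel: float = 0.05

    def __post_init__(self) -> None:
        if self.barrier_weight <= 0:
            raise InvalidInputError("barrier_weight must be > 0")
        if self.frobenius_weight < 0:
            raise InvalidInputError("frobenius_weight must be >= 0")
        if self.z_scaling not in ("none", "mean-normalize"):
            raise InvalidInputError(f"unknown z_scaling {self.z_scaling!r}")
        if not 0 <= self.edge_threshold_rel < 1:
            raise InvalidInputError("edge_threshold_rel must be in [0, 1)")


@dataclass
class MotionNetwork:
    """Learned adjacency for one (participant-side, movement)."""

    participant: str
    movement: int
    weights: np.ndarray
    edge_threshold_rel: float = 0.05
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.edges:
            self.edges = threshold_edges(self.weights, self.edge_threshold_rel)

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


def threshold_edges(W: np.ndarray, rel: float) -> set[tuple[int, int]]:
    """Pairs (i < j) whose weight exceeds ``rel * max(W)``."""
    wmax = float(W.max(initial=0.0))
    if wmax <= 0:
        return set()
    iu, ju = np.triu_indices(W.shape[0], 1)
    keep = W[iu, ju] > rel * wmax
    return {(int(i), int(j)) for i, j in zip(iu[keep], ju[keep])}


def objective(W: np.ndarray, Z: np.ndarray, cfg: GraphLearningConfig) -> float:
    """Value of the graph-learning objective at W (+inf on zero degrees)."""
    W = np.asarray(W, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if W.shape != Z.shape or W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise InvalidInputError("W and Z must be square matrices of equal shape")
    deg = W.sum(axis=1)
    if np.any(deg <= 0):
        return float("inf")
    smooth = 0.5 * float(np.sum(W * Z))
    barrier = -cfg.barrier_weight * float(np.log(deg).sum())
    frob = cfg.frobenius_weight * float(np.sum(W**2))
    return smooth + barrier + frob


def _scaled_z_vector(Z: np.ndarray, cfg: GraphLearningConfig):
    n = Z.shape[0]
    iu, ju = np.triu_indices(n, 1)
    z = Z[iu, ju].astype(float)
    scale = 1.0
    if cfg.z_scaling == "mean-normalize":
        mean = z.mean()
        if mean > 0:
            scale = mean
    return z / scale, iu, ju


def learn_graph(Z: np.ndarray, cfg: GraphLearningConfig = GraphLearningConfig()) -> np.ndarray:
    """Solve the graph-learning problem for one dissimilarity matrix.

    Returns a symmetric, non-negative, zero-diagonal adjacency matrix with
    strictly positive row sums.  Raises :class:`ConvergenceError` if the
    relative objective change has not dropped below ``cfg.tolerance``
    within ``cfg.max_iterations``.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    if Z.ndim != 2 or Z.shape[0] != Z.shape[1] or n < 2:
        raise InvalidInputError("Z must be a square matrix of size >= 2")
    if not np.all(np.isfinite(Z)):
        raise InvalidInputError("Z contains non-finite entries")
    z, iu, ju = _scaled_z_vector(Z, cfg)
    alpha = cfg.barrier_weight
    fr = 2.0 * cfg.frobenius_weight  # gamma ||W||_F^2 = fr ||w||^2

    # Condat-Vu step sizes: with sigma = tau the scheme converges when
    # 1/tau - tau * ||S||^2 >= L/2 = fr, and ||S||^2 = 2(n-1) for the
    # degree operator on a complete pair set.  tau solves the equality
    # with a 0.99 safety margin.
    s_norm2 = 2.0 * (n - 1)
    tau = (-fr + np.sqrt(fr**2 + 4.0 * 0.99 * s_norm2)) / (2.0 * s_norm2)
    sigma = tau

    def S(w):  # degrees from pair weights
        return np.bincount(iu, weights=w, minlength=n) + np.bincount(
            ju, weights=w, minlength=n
        )

    def St(v):  # adjoint
        return v[iu] + v[ju]

    w = np.full(z.shape, 1.0 / max(n - 1, 1))
    u = -alpha / S(w)  # a feasible dual point (gradient of the barrier)

    def obj(wv):
        d = S(wv)
        if np.any(d <= 0):
            return float("inf")
        return float(2.0 * z @ wv - alpha * np.log(d).sum() + fr * (wv @ wv))

    prev = obj(w)
    for _ in range(cfg.max_iterations):
        w_new = w - tau * (2.0 * fr * w + St(u))
        w_new -= 2.0 * tau * z
        np.maximum(w_new, 0.0, out=w_new)
        # dual prox via Moreau: prox of the conjugate of -alpha*sum(log)
        x = u + sigma * S(2.0 * w_new - w)
        u = x - 0.5 * (x + np.sqrt(x * x + 4.0 * sigma * alpha))
        w = w_new
        cur = obj(w)
        if np.isfinite(cur) and np.isfinite(prev):
            denom = max(abs(prev), 1e-12)
            if abs(cur - prev) / denom < cfg.tolerance:
                break
        prev = cur
    else:
        denom = max(abs(prev), 1e-12)
        raise ConvergenceError(
            "graph learning did not converge within "
            f"{cfg.max_iterations} iterations (last relative change "
            f"{abs(cur - prev) / denom:.3e})"
        )
    W = np.zeros((n, n))
    W[iu, ju] = w
    W += W.T
    return W


def build_network(
    series,
    w: PenaltyWeights = PenaltyWeights(),
    cfg: GraphLearningConfig = GraphLearningConfig(),
    participant: str = "",
    movement: int = 0,
) -> MotionNetwork:
    """Dissimilarity + graph learning for one recording's channel set.

    The synchrony term of the dissimilarity is computed on amplitude-
    normalized curves so that the null/constant penalties are on the same
    scale (see :func:`motionsync.dissimilarity.dissimilarity_matrix`).
    """
    Z = dissimilarity_matrix(series, w, normalize_synchrony=True)
    W = learn_graph(Z, cfg)
    return MotionNetwork(
        participant=participant,
        movement=movement,
        weights=W,
        edge_threshold_rel=cfg.edge_threshold_rel,
    )


def build_all_networks(
    cohort: Cohort,
    w: PenaltyWeights = PenaltyWeights(),
    cfg: GraphLearningConfig = GraphLearningConfig(),
) -> list[MotionNetwork]:
    """One network per (participant-side, movement), participant-major order."""
    nets: list[MotionNetwork] = []
    for p in cohort.participants:
        for m in range(cohort.n_movements):
            try:
                series = cohort.movement_series(p.id, m)
                nets.append(
                    build_network(series, w, cfg, participant=p.id, movement=m)
                )
            except Exception as exc:
                raise type(exc)(
                    f"network build failed for participant {p.id!r}, "
                    f"movement {m}: {exc}"
                ) from exc
    return nets


# --------------------------------------------------------------------------
# serialization (GraphML via networkx, plus a JSON adjacency format)
# --------------------------------------------------------------------------


def network_to_nx(net: MotionNetwork, angles: list[JointAngle] | None = None) -> nx.Graph:
    g = nx.Graph(participant=net.participant, movement=int(net.movement))
    n = net.n_vertices
    for i in range(n):
        attrs = {}
        if angles is not None:
            a = angles[i]
            attrs = {"name": a.name, "region": a.region, "display_rank": a.display_rank}
        g.add_node(i, **attrs)
    for i, j in sorted(net.edges):
        g.add_edge(i, j, weight=float(net.weights[i, j]))
    return g


def save_network_graphml(net: MotionNetwork, path, angles=None) -> None:
    nx.write_graphml(network_to_nx(net, angles), str(path))


def load_network_graphml(path, n_vertices: int | None = None) -> MotionNetwork:
    g = nx.read_graphml(str(path), node_type=int)
    n = n_vertices or (max(g.nodes) + 1)
    W = np.zeros((n, n))
    for i, j, d in g.edges(data=True):
        W[i, j] = W[j, i] = float(d["weight"])
    return MotionNetwork(
        participant=g.graph.get("participant", ""),
        movement=int(g.graph.get("movement", 0)),
        weights=W,
        edges={tuple(sorted((i, j))) for i, j in g.edges()},
    )


def save_network_json(net: MotionNetwork, path) -> None:
    payload = {
        "participant": net.participant,
        "movement": int(net.movement),
        "n_vertices": int(net.n_vertices),
        "edge_threshold_rel": net.edge_threshold_rel,
        "edges": [
            [int(i), int(j), float(net.weights[i, j])] for i, j in sorted(net.edges)
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_network_json(path) -> MotionNetwork:
    payload = json.loads(Path(path).read_text())
    n = payload["n_vertices"]
    W = np.zeros((n, n))
    edges = set()
    for i, j, wij in payload["edges"]:
        W[i, j] = W[j, i] = wij
        edges.add((i, j))
    return MotionNetwork(
        participant=payload["participant"],
        movement=payload["movement"],
        weights=W,
        edge_threshold_rel=payload.get("edge_threshold_rel", 0.05),
        edges=edges,
    )
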