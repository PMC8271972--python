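"""Per-series measures, group summary curves, network features, projections.

Three complementary 2-D views of a cohort are supported: PCA of per-network
centrality feature vectors, PCA of the raw (normalized) motion curves, and
classical MDS of convolutional-autoencoder embeddings.  Group summaries
(pointwise mean and standard deviation curves) feed the comparison plots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

from .cohort import TimeSeries
from .errors import InvalidInputError
from .graph_learning import MotionNetwork

ENTROPY_BINS = 100


def series_measures(values) -> tuple[float, float, float]:
    """(mean, entropy, energy) of one trace.

    Entropy is the natural-log Shannon entropy of the 100-bin value
    histogram over the series' own [min, max] range, normalized to
    probabilities; a constant series occupies a single bin and scores 0.
    Energy is the sum of squared values.
    """
    x = np.asarray(getattr(values, "values", values), dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InvalidInputError("expected a non-empty 1-D series")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("series contains non-finite values")
    mean = float(x.mean())
    energy = float(np.sum(x**2))
    if np.ptp(x) == 0:
        entropy = 0.0
    else:
        counts, _ = np.histogram(x, bins=ENTROPY_BINS)
        p = counts[counts > 0] / x.size
        entropy = float(-(p * np.log(p)).sum())
    return mean, entropy, energy


@dataclass
class GroupSummary:
    """Pointwise mean/sd curves of one group for one (movement, angle).

    ``display_length`` is the mean original duration in Proportional mode
    (groups keep their real time extent) or the common length in
    SameLength mode (profiles directly comparable).
    """

    mean_curve: np.ndarray
    sd_curve: np.ndarray
    group: str
    display_length: float
    mode: str = "SameLength"


def group_summary(series: list[TimeSeries], mode: str = "SameLength", group: str = "") -> GroupSummary:
    """Summarize one (movement, angle) across the participants of a group."""
    if mode not in ("Proportional", "SameLength"):
        raise InvalidInputError(f"unknown summary mode {mode!r}")
    if not series:
        raise InvalidInputError("group summary needs at least one series")
    X = np.stack([np.asarray(s.values, dtype=float) for s in series])
    if len({x.size for x in X}) != 1:
        raise InvalidInputError("summary expects common-length series")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if mode == "Proportional":
        display = float(np.mean([s.original_length for s in series]))
    else:
        display = float(X.shape[1])
    return GroupSummary(mean, sd, group, display, mode)


def _eigencentrality_per_component(g: nx.Graph, n: int) -> np.ndarray:
    """Principal-eigenvector centrality, computed per connected component.

    Each non-trivial component gets the (non-negative, L2-normalized)
    leading eigenvector of its weighted adjacency block; isolated nodes
    score 0.
    """
    out = np.zeros(n)
    W = nx.to_numpy_array(g, nodelist=range(n), weight="weight")
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) < 2:
            continue
        block = W[np.ix_(nodes, nodes)]
        vals, vecs = np.linalg.eigh(block)
        v = vecs[:, -1]
        v = np.abs(v)
        norm = np.linalg.norm(v)
        if norm > 0:
            v = v / norm
        out[nodes] = v
    return out


def network_features(net: MotionNetwork) -> np.ndarray:
    """Feature vector [degree | closeness | eigencentrality | clustering].

    All four blocks have length N_A and are computed on the thresholded
    weighted graph; the vector has length 4 * N_A.  Closeness uses
    1/weight as edge distance (heavier synchronization = shorter
    distance); isolated nodes score 0 in every block.
    """
    n = net.n_vertices
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i, j in net.edges:
        wij = float(net.weights[i, j])
        g.add_edge(i, j, weight=wij, dist=1.0 / wij if wij > 0 else np.inf)
    degree = np.array([g.degree(i, weight="weight") for i in range(n)], dtype=float)
    closeness = np.array(
        [nx.closeness_centrality(g, u=i, distance="dist") for i in range(n)]
    )
    eig = _eigencentrality_per_component(g, n)
    clus_map = nx.clustering(g, weight="weight")
    clustering = np.array([clus_map[i] for i in range(n)], dtype=float)
    return np.concatenate([degree, closeness, eig, clustering])


def participant_feature_vector(nets: list[MotionNetwork]) -> np.ndarray:
    """Concatenate per-movement network features (movement order)."""
    return np.concatenate([network_features(n) for n in sorted(nets, key=lambda n: n.movement)])


def _fix_signs(components: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    for c in range(components.shape[0]):
        idx = np.argmax(np.abs(components[c]))
        if components[c, idx] < 0:
            scores[:, c] = -scores[:, c]
    return scores


def pca_project(vectors, dims: int = 2) -> np.ndarray:
    """Mean-centered PCA scores on the top ``dims`` components."""
    X = np.stack([np.asarray(v, dtype=float) for v in vectors])
    if X.shape[0] < 2:
        raise InvalidInputError("PCA needs at least 2 vectors")
    if np.allclose(X, X[0]):
        raise InvalidInputError("PCA input is degenerate (all vectors identical)")
    k = min(dims, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    scores = _fix_signs(pca.components_, scores)
    if k < dims:
        scores = np.hstack([scores, np.zeros((X.shape[0], dims - k))])
    return scores


def mds_project(vectors, dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS on Euclidean distances.

    Double-centers the squared distance matrix and embeds with the top
    eigenpairs, so an intrinsically ``dims``-dimensional configuration is
    recovered up to a rigid transform.
    """
    X = np.stack([np.asarray(v, dtype=float) for v in vectors])
    m = X.shape[0]
    if m < 3:
        raise InvalidInputError("MDS needs at least 3 vectors")
    sq = np.sum(X**2, axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(D2, 0.0, out=D2)
    if np.allclose(D2, 0.0):
        warnings.warn("all input vectors identical; MDS places every point at 0")
        return np.zeros((m, dims))
    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:dims]
    lam = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(lam)[None, :]
    return _fix_signs(coords.T.copy(), coords)
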