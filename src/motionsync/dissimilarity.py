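"""Pairwise dissimilarity between joint-angle traces.

The graph-learning step wants a dissimilarity Z that is small exactly when
two channels move together and that never rewards motionless channels.  For
channels i, j (equal-length traces t_i, t_j) it is the weighted sum of
three terms:

    z1 = ||t_i - t_j||^2          squared Euclidean distance (synchrony)
    z2 = 2 if either trace is null (all-zero), else 0
    z3 = exp(-TV(t_i)) + exp(-TV(t_j))

where TV is the total variation (sum of absolute consecutive differences).
z2 pushes all-zero channels away from everything; z3 does the same,
smoothly, for near-constant channels (TV ~ 0 gives z3 ~ 2, busy channels
give z3 ~ 0).  Default weights are (1, 1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

#: tolerance on max |value| below which a series counts as null; exact-zero
#: tests are fragile after spline resampling
NULL_TOL = 1e-8


@dataclass(frozen=True)
class PenaltyWeights:
    """Weights of the three dissimilarity terms (all non-negative)."""

    w1: float = 1.0
    w2: float = 1.0
    w3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise InvalidInputError("penalty weights must be non-negative")


def _values(series) -> np.ndarray:
    x = np.asarray(getattr(series, "values", series), dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InvalidInputError("expected a non-empty 1-D series")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("series contains non-finite values")
    return x


def total_variation(values) -> float:
    """Sum of absolute consecutive differences; 0 for constant input."""
    x = _values(values)
    return float(np.abs(np.diff(x)).sum())


def is_null_series(values, tol: float = NULL_TOL) -> bool:
    """True iff every sample is within ``tol`` of zero."""
    x = np.asarray(getattr(values, "values", values), dtype=float)
    if x.size == 0:
        return True
    return bool(np.max(np.abs(x)) <= tol)


def pair_dissimilarity(
    ti, tj, w: PenaltyWeights = PenaltyWeights(), tol: float = NULL_TOL
) -> tuple[float, float, float, float]:
    """Return (z1, z2, z3, Z) for a pair of equal-length traces."""
    xi, xj = _values(ti), _values(tj)
    if xi.size != xj.size:
        raise InvalidInputError(
            f"series length mismatch: {xi.size} vs {xj.size} (resample first)"
        )
    z1 = float(np.sum((xi - xj) ** 2))
    z2 = 2.0 if (is_null_series(xi, tol) or is_null_series(xj, tol)) else 0.0
    z3 = float(np.exp(-total_variation(xi)) + np.exp(-total_variation(xj)))
    z = w.w1 * z1 + w.w2 * z2 + w.w3 * z3
    return z1, z2, z3, z


def dissimilarity_matrix(
    series,
    w: PenaltyWeights = PenaltyWeights(),
    tol: float = NULL_TOL,
    normalize_synchrony: bool = False,
) -> np.ndarray:
    """Symmetric dissimilarity matrix with exact-zero diagonal.

    ``series`` is a list of equal-length traces (or TimeSeries).  Off-
    diagonal entries equal :func:`pair_dissimilarity`; the diagonal is
    zero by construction.

    With ``normalize_synchrony=True`` the squared-Euclidean term z1 is
    computed on mean-centered, unit-L2-normalized curves, so z1 = 2(1 -
    rho) with rho the Pearson correlation: synchrony becomes scale- and
    offset-invariant and is capped at 4.  Raw joint-angle curves give z1
    values of order 1e5-1e7 deg^2, against which the fixed z2 = 2 and
    z3 <= 2 penalties are invisible; the normalization puts all three
    terms on one O(1) scale so the penalties can do their job.  A
    motionless curve (zero after centering: null or constant) has no
    defined correlation with anything, so every pair involving one is
    assigned the maximal z1 = 4 - it synchronizes with nothing, including
    other motionless curves.  z2/z3 always see the raw curves (total
    variation of a normalized curve would be spuriously small).
    """
    X = np.stack([_values(s) for s in series])
    n = X.shape[0]
    null = np.array([is_null_series(x, tol) for x in X])
    if normalize_synchrony:
        Xc = X - X.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Xc, axis=1)
        flat = norms <= tol * np.sqrt(X.shape[1])
        X1 = np.where(
            flat[:, None], 0.0, Xc / np.maximum(norms[:, None], 1e-300)
        )
        z1 = 2.0 - 2.0 * (X1 @ X1.T)
        z1[flat, :] = 4.0
        z1[:, flat] = 4.0
        np.clip(z1, 0.0, 4.0, out=z1)
    else:
        sq = np.sum(X**2, axis=1)
        z1 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
        np.maximum(z1, 0.0, out=z1)
    z2 = np.where(null[:, None] | null[None, :], 2.0, 0.0)
    ev = np.exp(-np.abs(np.diff(X, axis=1)).sum(axis=1))
    z3 = ev[:, None] + ev[None, :]
    Z = w.w1 * z1 + w.w2 * z2 + w.w3 * z3
    Z = 0.5 * (Z + Z.T)
    np.fill_diagonal(Z, 0.0)
    return Z
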