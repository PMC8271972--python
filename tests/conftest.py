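"""Shared fixtures and the independent convex oracle used by solver tests."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from motionsync import SyntheticConfig, generate_cohort
from motionsync.graph_learning import GraphLearningConfig


def solve_oracle(Z: np.ndarray, cfg: GraphLearningConfig) -> np.ndarray:
    """Independent solution of the graph-learning problem.

    Bound-constrained quasi-Newton (L-BFGS-B) on the upper-triangular
    weight vector; shares no code with the primal-dual solver it checks.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    iu, ju = np.triu_indices(n, 1)
    z = Z[iu, ju]
    if cfg.z_scaling == "mean-normalize" and z.mean() > 0:
        z = z / z.mean()
    alpha = cfg.barrier_weight
    fr = 2.0 * cfg.frobenius_weight

    def degrees(w):
        return np.bincount(iu, w, n) + np.bincount(ju, w, n)

    def f(w):
        d = degrees(w)
        if np.any(d <= 0):
            return 1e12
        return 2 * z @ w - alpha * np.log(d).sum() + fr * w @ w

    def grad(w):
        d = degrees(w)
        gd = -alpha / np.maximum(d, 1e-300)
        return 2 * z + gd[iu] + gd[ju] + 2 * fr * w

    w0 = np.full(z.shape, 1.0 / (n - 1))
    res = minimize(
        f,
        w0,
        jac=grad,
        method="L-BFGS-B",
        bounds=[(1e-15, None)] * len(z),
        options=dict(maxiter=20000, ftol=1e-18, gtol=1e-14),
    )
    W = np.zeros((n, n))
    W[iu, ju] = res.x
    return W + W.T


def random_dissimilarity(rng: np.random.Generator, n: int) -> np.ndarray:
    Z = rng.uniform(0.0, 10.0, (n, n))
    Z = 0.5 * (Z + Z.T)
    np.fill_diagonal(Z, 0.0)
    return Z


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    """A miniature cohort configuration used across module tests."""
    return SyntheticConfig(
        n_stroke_L=2,
        n_stroke_R=1,
        n_ctrl=2,
        n_movements=2,
        n_angles=5,
        couplings={"stroke": [((0, 1), 0)], "control": [((2, 3), 0)]},
        duration_range=(50, 120),
        m_max=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    cohort, truth = generate_cohort(small_cfg)
    cohort.resample_all()
    return cohort, truth
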