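"""Idealized model of the SCA matrix's top eigenmode.

Because the SCA matrix takes absolute values of covariances, its
off-diagonal entries acquire a positive bias even when the underlying
positions are uncorrelated.  An idealized matrix capturing this is

    M_ii = Delta_i,      M_ij = d_i d_j x   (i != j),

with d_i = sqrt(Delta_i) and a single off-diagonal scale x >= 0.  The
eigenvalue equation gives an exact self-consistency relation for any
eigenpair (lambda, v):

    v_i (lambda - Delta_i (1 - x)) = x d_i sum_j d_j v_j,

from which, when lambda_top dominates every Delta_i,

    lambda_top ~ x / (1 + x) * sum_i Delta_i,
    v_i,top    ~ alpha * sqrt(Delta_i),

i.e. the top eigenvector tracks the square root of the diagonal — the
empirical phenomenon seen on protein alignments.  The module also
estimates x from a real SCA matrix and runs the scaling experiment that
separates sampling noise (x decays with alignment depth N) from genuine
uniform correlations such as shared ancestry (x roughly constant in N).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable

import numpy as np

from .sca import SCAMatrix, SpectralResult, spectral

logger = logging.getLogger(__name__)


class TheoryError(ValueError):
    pass


@dataclasses.dataclass
class IdealizedModel:
    """Diagonal levels ``delta`` (> 0) and off-diagonal scale ``x``."""

    delta: np.ndarray
    x: float

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.ndim != 1 or self.delta.size < 2:
            raise TheoryError("delta must be a vector of length >= 2")
        if np.any(self.delta <= 0):
            raise TheoryError("diagonal levels must be positive")
        if self.x < 0:
            raise TheoryError("off-diagonal scale must be nonnegative")

    @property
    def n(self) -> int:
        return self.delta.size

    @property
    def d(self) -> np.ndarray:
        return np.sqrt(self.delta)


def build_idealized_matrix(model: IdealizedModel) -> np.ndarray:
    """The n x n matrix with Delta on the diagonal and d_i d_j x off it."""
    d = model.d
    M = model.x * np.outer(d, d)
    np.fill_diagonal(M, model.delta)
    return M


def top_mode_approximations(
    model: IdealizedModel,
) -> tuple[float, np.ndarray, bool]:
    """Approximate top eigenpair of the idealized matrix.

    Returns ``(lambda_approx, v_approx, in_regime)`` with
    ``lambda_approx = x/(1+x) * sum(Delta)`` and ``v_approx`` proportional
    to sqrt(Delta), unit-normalised, nonnegative.  ``in_regime`` is False
    when the approximation's premise (lambda_top well above every
    diagonal level) fails, e.g. at x = 0.
    """
    lam = model.x / (1.0 + model.x) * float(model.delta.sum())
    v = model.d / np.linalg.norm(model.d)
    in_regime = lam > float(model.delta.max())
    if not in_regime:
        logger.warning(
            "top-mode approximation out of regime: lambda_approx=%.3g "
            "<= max diagonal %.3g", lam, model.delta.max(),
        )
    return lam, v, in_regime


def eigen_relation_residual(
    model: IdealizedModel, eigenvalue: float, eigenvector: np.ndarray
) -> float:
    """Max absolute residual of the exact self-consistency relation.

    For any exact eigenpair of the idealized matrix,
    ``v_i (lambda - Delta_i (1 - x)) - x d_i sum_j d_j v_j = 0``
    holds identically; a perturbed eigenvector breaks it.
    """
    v = np.asarray(eigenvector, dtype=float)
    d = model.d
    s = float(d @ v)
    residual = v * (eigenvalue - model.delta * (1.0 - model.x)) - model.x * d * s
    return float(np.max(np.abs(residual)))


def estimate_offdiag_scale(C: SCAMatrix) -> float:
    """Estimate the off-diagonal scale x of an SCA matrix.

    x_hat = mean over i < j of C_ij / sqrt(C_ii C_jj); pairs with a zero
    diagonal entry are excluded with a warning.
    """
    n = C.n
    diag = C.diag
    ok = diag > 0
    if not np.all(ok):
        logger.warning(
            "excluding %d column(s) with zero diagonal from x estimate",
            int((~ok).sum()),
        )
    idx = np.flatnonzero(ok)
    if idx.size < 2:
        raise TheoryError("need at least 2 columns with positive diagonal")
    sub = C.C[np.ix_(idx, idx)]
    d = np.sqrt(diag[idx])
    ratio = sub / np.outer(d, d)
    iu = np.triu_indices(idx.size, k=1)
    return float(ratio[iu].mean())


def scaling_experiment(
    generator: Callable[[int, int], SCAMatrix],
    N_values: list[int],
    replicates: int,
    seed: int,
) -> dict:
    """Fit the power law of x_hat versus alignment depth N.

    ``generator(N, seed)`` must return an SCA matrix computed from a fresh
    synthetic alignment of N sequences.  For each N, ``replicates``
    matrices are generated (seeds derived from ``seed``) and their x_hat
    averaged; a least-squares line through (log N, log x_hat) gives the
    exponent.  Sampling noise alone makes x_hat decay with N; genuine
    uniform correlations (e.g. shared ancestry) keep it roughly flat.
    """
    if len(N_values) < 3:
        raise TheoryError("need at least 3 values of N")
    x_means = []
    per_N = {}
    for i, N in enumerate(N_values):
        xs = [
            estimate_offdiag_scale(
                generator(N, seed + 1000 * i + r)
            )
            for r in range(replicates)
        ]
        per_N[N] = xs
        x_means.append(float(np.mean(xs)))
    x_means = np.asarray(x_means)
    if np.any(x_means <= 0):
        raise TheoryError("nonpositive x_hat; cannot fit a power law")
    logN = np.log(np.asarray(N_values, dtype=float))
    logx = np.log(x_means)
    slope, intercept = np.polyfit(logN, logx, 1)
    return {
        "exponent": float(slope),
        "intercept": float(intercept),
        "x_means": dict(zip(N_values, x_means.tolist())),
        "per_N": per_N,
    }
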