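"""Projection-method statistical coupling analysis.

The projection method collapses the 20-letter amino-acid dimension to one
number per alignment cell before computing covariances.  For alignment
entry ``a_ki`` (sequence k, column i):

    x~_ki = phi_i(a) f_i(a) / sqrt( sum_{b != gap} phi_i(b)^2 f_i(b)^2 )

with ``x~_ki = 0`` at gaps, and conservation-derived positional weights

    phi_i(a) = ln[ f_i(a) (1 - q(a)) / ((1 - f_i(a)) q(a)) ].

The SCA matrix is the element-wise absolute value of the population
covariance matrix of the projected alignment,

    C~_ij = | (1/N) sum_k x~_ki x~_kj - (1/N^2)(sum_k x~_ki)(sum_l x~_lj) |.

Because of the absolute value, the off-diagonal entries acquire a positive
bias, which ties the top eigenvector to the diagonal (i.e. to
conservation); the sector is read off as the top-loading quarter of the
leading eigenvector's components.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .alignment import Alignment, GAP_INDEX
from .conservation import ConservationProfile, FrequencyModel

logger = logging.getLogger(__name__)

_SYM_TOL = 1e-10


class SCAError(ValueError):
    pass


@dataclasses.dataclass
class PositionalWeights:
    """Log-odds weights ``phi`` (n x 20, gap excluded) with clamp bound."""

    phi: np.ndarray
    clamp: float

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.all(np.isfinite(self.phi)):
            raise SCAError("positional weights must be finite")


@dataclasses.dataclass
class ProjectedAlignment:
    """The numeric N x n matrix of projected alignment values."""

    xt: np.ndarray

    def __post_init__(self) -> None:
        self.xt = np.asarray(self.xt, dtype=float)
        if self.xt.ndim != 2:
            raise SCAError("projected alignment must be 2-D")


@dataclasses.dataclass
class SCAMatrix:
    """Symmetric nonnegative n x n coupling matrix."""

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise SCAError("SCA matrix must be square")
        if np.max(np.abs(self.C - self.C.T)) > _SYM_TOL:
            raise SCAError("SCA matrix must be symmetric")

    @property
    def diag(self) -> np.ndarray:
        return np.diag(self.C)

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclasses.dataclass
class SpectralResult:
    """Eigenpairs sorted by descending eigenvalue, unit-norm vectors with
    nonnegative component sum."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns are eigenvectors

    @property
    def top_eigenvector(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    @property
    def top_eigenvalue(self) -> float:
        return float(self.eigenvalues[0])


@dataclasses.dataclass
class Sector:
    """Top-eigenvector sector: column indices and their loadings."""

    positions: list[int]
    scores: np.ndarray
    fraction: float


def positional_weights(
    model: FrequencyModel, clamp: float = 0.001
) -> PositionalWeights:
    """Conservation-derived log-odds weights for the 20 amino acids.

    Frequencies are clamped to ``[clamp, 1 - clamp]`` before taking the
    log-odds, since the weight diverges at frequencies 0 and 1; within the
    clamp band the exact log-odds form is returned.
    """
    if not 0 < clamp < 0.5:
        raise SCAError("clamp must be in (0, 0.5)")
    # the weights compare against the amino-acid database background; undo
    # any gap rescaling applied for the conservation computation
    q = model.q[:20]
    total = q.sum()
    if total <= 0:
        raise SCAError("background has no amino-acid mass")
    if abs(total - 1.0) > 1e-12:
        q = q / total
    if np.any(q <= 0) or np.any(q >= 1):
        bad = np.flatnonzero((q <= 0) | (q >= 1))
        raise SCAError(
            f"background entries at indices {bad.tolist()} are 0 or 1; "
            "positional weight undefined"
        )
    f = np.clip(model.f[:, :20], clamp, 1.0 - clamp)
    phi = np.log(f * (1.0 - q)[None, :] / ((1.0 - f) * q[None, :]))
    # exact zero where f == q (clamping cannot move an interior frequency)
    phi[np.isclose(model.f[:, :20], q[None, :], rtol=0, atol=0)] = 0.0
    return PositionalWeights(phi=phi, clamp=clamp)


def project_alignment(
    aln: Alignment, model: FrequencyModel, weights: PositionalWeights
) -> ProjectedAlignment:
    """Collapse each alignment cell to a single weighted number.

    Gap cells project to 0.  A column whose weighted-frequency norm
    vanishes (e.g. every frequency equal to background) projects to an
    all-zero column, with a warning.
    """
    mat = aln.to_matrix()
    N, n = mat.shape
    if model.f.shape[0] != n or weights.phi.shape[0] != n:
        raise SCAError("alignment, frequencies and weights disagree on n")
    wf = weights.phi * model.f[:, :20]  # n x 20
    norm = np.sqrt((wf**2).sum(axis=1))  # per column
    zero = norm == 0
    if np.any(zero):
        logger.warning(
            "projection: %d column(s) have zero weighted-frequency norm "
            "and project to zero", int(zero.sum()),
        )
    safe = np.where(zero, 1.0, norm)
    values = wf / safe[None, :].T  # n x 20 projected value per symbol
    values[zero, :] = 0.0
    xt = np.zeros((N, n))
    non_gap = mat != GAP_INDEX
    cols = np.broadcast_to(np.arange(n), (N, n))
    xt[non_gap] = values[cols[non_gap], mat[non_gap]]
    return ProjectedAlignment(xt=xt)


def sca_matrix(projected: ProjectedAlignment) -> SCAMatrix:
    """Absolute population covariance of the projected alignment."""
    xt = projected.xt
    N = xt.shape[0]
    if N < 2:
        raise SCAError("need at least 2 sequences for a covariance")
    centered = xt - xt.mean(axis=0, keepdims=True)
    C = np.abs(centered.T @ centered / N)
    C = 0.5 * (C + C.T)  # exact symmetry against roundoff
    return SCAMatrix(C=C)


def spectral(C: SCAMatrix, m: int | None = None) -> SpectralResult:
    """Top-``m`` eigenpairs of the SCA matrix.

    Eigenvalues descending; each eigenvector unit-norm and oriented so its
    component sum is nonnegative.
    """
    n = C.n
    if m is None:
        m = n
    if not 1 <= m <= n:
        raise SCAError(f"m must be in [1, {n}]")
    evals, evecs = np.linalg.eigh(C.C)
    order = np.argsort(evals)[::-1]
    evals = evals[order][:m]
    evecs = evecs[:, order][:, :m]
    signs = np.where(evecs.sum(axis=0) < 0, -1.0, 1.0)
    evecs = evecs * signs[None, :]
    return SpectralResult(eigenvalues=evals, eigenvectors=evecs)


def sector_size(n: int, fraction: float = 0.25) -> int:
    """Number of sector positions under the ~25% rule: round(fraction*n),
    rounding half up."""
    return int(np.floor(fraction * n + 0.5))


def extract_sector(
    spec: SpectralResult, n: int, fraction: float = 0.25
) -> Sector:
    """Rank-based sector: the ``round(fraction * n)`` columns with the
    largest top-eigenvector components (ties to the lower index)."""
    k = sector_size(n, fraction)
    if k == 0:
        raise SCAError(f"sector size rounds to 0 (n={n}, fraction={fraction})")
    v = spec.top_eigenvector
    if len(v) != n:
        raise SCAError("eigenvector length does not match n")
    order = sorted(range(n), key=lambda j: (-v[j], j))
    positions = order[:k]
    return Sector(positions=positions, scores=v.copy(), fraction=fraction)


def top_k_positions(spec: SpectralResult, k: int) -> list[int]:
    """The k columns with the largest top-eigenvector components."""
    v = spec.top_eigenvector
    if not 1 <= k <= len(v):
        raise SCAError(f"k must be in [1, {len(v)}]")
    return sorted(range(len(v)), key=lambda j: (-v[j], j))[:k]


def topvec_diag_correlation(
    C: SCAMatrix,
    spec: SpectralResult,
    conservation: ConservationProfile | None = None,
) -> dict:
    """Pearson correlation of the top eigenvector with sqrt(diagonal) and,
    optionally, with conservation.

    Returns a dict with keys ``r_sqrt_diag``, ``r_conservation`` (None when
    an input has zero variance) and the paired arrays for plotting.
    """
    if C.n < 3:
        raise SCAError("need at least 3 columns for a meaningful correlation")
    v = spec.top_eigenvector
    sq = np.sqrt(C.diag)

    def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
        if np.std(a) == 0 or np.std(b) == 0:
            logger.warning("zero-variance input; correlation undefined")
            return None
        return float(np.corrcoef(a, b)[0, 1])

    out = {
        "r_sqrt_diag": _pearson(v, sq),
        "v_top": v,
        "sqrt_diag": sq,
        "r_conservation": None,
        "conservation": None,
    }
    if conservation is not None:
        out["r_conservation"] = _pearson(v, conservation.D)
        out["conservation"] = conservation.D
    return out
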