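"""Per-column frequencies, gap-aware background, and relative-entropy
conservation.

Conservation of column ``i`` is the Kullback–Leibler divergence

    D_i = sum_a f_i(a) ln( f_i(a) / q(a) )

between the column's empirical amino-acid distribution ``f_i`` (gap
included) and a background distribution ``q``.  Because the sum runs over
the gap symbol too, ``q`` needs a gap entry; by default the background gap
frequency is set to the alignment-wide mean gap fraction and the 20
amino-acid entries are rescaled to keep the total at 1 (``average_gap``
mode).  Alternatively gapped cells can be excluded column-wise
(``ignore_gap`` mode); the two agree on gap-free alignments.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from .alignment import Alignment, GAP_INDEX, N_SYMBOLS

GapMode = Literal["average_gap", "ignore_gap"]

_TOL = 1e-9


class ConservationError(ValueError):
    pass


@dataclasses.dataclass
class FrequencyModel:
    """Column frequencies ``f`` (n x 21) and background ``q`` (21,)."""

    f: np.ndarray
    q: np.ndarray
    gap_mode: GapMode = "average_gap"

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.f.ndim != 2 or self.f.shape[1] != N_SYMBOLS:
            raise ConservationError(f"f must be n x {N_SYMBOLS}")
        if self.q.shape != (N_SYMBOLS,):
            raise ConservationError(f"q must have length {N_SYMBOLS}")
        if np.any(self.f < -_TOL) or np.any(self.f > 1 + _TOL):
            raise ConservationError("column frequencies outside [0, 1]")
        if not np.allclose(self.f.sum(axis=1), 1.0, atol=_TOL):
            raise ConservationError("column frequencies must sum to 1")
        if np.any(self.q < -_TOL):
            raise ConservationError("background entries must be >= 0")
        if abs(self.q.sum() - 1.0) > _TOL:
            raise ConservationError("background must sum to 1")


@dataclasses.dataclass
class ConservationProfile:
    """Per-column conservation values, in nats."""

    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D < -1e-12):
            raise ConservationError("conservation values must be nonnegative")

    def __len__(self) -> int:
        return len(self.D)


def column_frequencies(aln: Alignment) -> np.ndarray:
    """Empirical symbol frequencies per column, gap included (n x 21)."""
    mat = aln.to_matrix()
    N, n = mat.shape
    f = np.zeros((n, N_SYMBOLS))
    for s in range(N_SYMBOLS):
        f[:, s] = (mat == s).sum(axis=0)
    return f / N


def background_with_gap(
    aln: Alignment,
    q_aa: np.ndarray,
    gap_mode: GapMode = "average_gap",
) -> np.ndarray:
    """Extend a 20-amino-acid background to the 21-symbol alphabet.

    ``average_gap``: q(gap) = mean column gap fraction of the alignment;
    amino-acid entries scaled by 1 - q(gap).  ``ignore_gap``: q(gap) = 0.
    """
    q_aa = np.asarray(q_aa, dtype=float)
    if q_aa.shape != (20,):
        raise ConservationError("q_aa must have 20 entries")
    if abs(q_aa.sum() - 1.0) > _TOL:
        raise ConservationError("q_aa must sum to 1 over the amino acids")
    q = np.zeros(N_SYMBOLS)
    if gap_mode == "average_gap":
        f = column_frequencies(aln)
        q_gap = float(f[:, GAP_INDEX].mean())
        q[:20] = q_aa * (1.0 - q_gap)
        q[GAP_INDEX] = q_gap
    elif gap_mode == "ignore_gap":
        q[:20] = q_aa
    else:
        raise ConservationError(f"unknown gap_mode {gap_mode!r}")
    return q


def frequency_model(
    aln: Alignment,
    q_aa: np.ndarray,
    gap_mode: GapMode = "average_gap",
) -> FrequencyModel:
    """Build the frequency model for an alignment.

    In ``ignore_gap`` mode, gapped cells are excluded column-wise: each
    column's frequencies are renormalised over its non-gap cells (columns
    that are entirely gaps keep a unit mass on the gap slot so the model
    invariants hold; such columns carry no conservation signal).
    """
    f = column_frequencies(aln)
    q = background_with_gap(aln, q_aa, gap_mode)
    if gap_mode == "ignore_gap":
        non_gap = 1.0 - f[:, GAP_INDEX]
        f = f.copy()
        ok = non_gap > 0
        f[ok, :20] = f[ok, :20] / non_gap[ok, None]
        f[ok, GAP_INDEX] = 0.0
    return FrequencyModel(f=f, q=q, gap_mode=gap_mode)


def conservation_profile(model: FrequencyModel) -> ConservationProfile:
    """Relative-entropy conservation ``D_i`` per column (natural log).

    Terms with ``f_i(a) = 0`` contribute 0.  A column frequency that is
    positive where the background is zero makes the divergence infinite
    and is reported as an error naming the column and symbol.
    """
    from .alignment import ALPHABET

    f, q = model.f, model.q
    bad = (f > 0) & (q[None, :] <= 0)
    if np.any(bad):
        i, a = map(int, np.argwhere(bad)[0])
        raise ConservationError(
            f"column {i}: symbol {ALPHABET[a]!r} has positive frequency "
            "but zero background; D is undefined"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(np.where(f > 0, f, 1.0) / q), 0.0)
    D = terms.sum(axis=1)
    # KL >= 0; clip away roundoff at the f == q boundary
    D = np.where(D < 0, np.maximum(D, -1e-12), D)
    return ConservationProfile(D=D)


def most_prevalent_frequency(model: FrequencyModel) -> np.ndarray:
    """Alternative conservation score: frequency of the most prevalent
    amino acid per column (gap excluded from the maximisation)."""
    return model.f[:, :20].max(axis=1)


def top_conserved_set(D: ConservationProfile, k: int) -> list[int]:
    """Indices of the ``k`` most conserved columns.

    Ties broken toward the lower column index; output ordered by
    descending ``D`` then ascending index.
    """
    n = len(D)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = sorted(range(n), key=lambda j: (-D.D[j], j))
    return order[:k]
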