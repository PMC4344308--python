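"""Seeded synthetic alignments and mutational-effect data.

Three alignment generators cover the statistical regimes the analysis
distinguishes:

``independent``
    Columns are independent categorical draws: column i emits a dominant
    residue with probability ``profile[i]`` and spreads the remainder
    uniformly over the other 19 amino acids.  Heterogeneous profiles give
    heterogeneous conservation with no correlation structure beyond
    sampling noise.

``planted_sector``
    A hidden binary state per sequence (equiprobable) modulates the
    dominant-residue frequency of a designated column group: in state 0
    the dominant mass is ``profile + delta``, in state 1 it is
    ``profile - delta``, with ``delta = coupling * min(profile, 1 -
    profile)``.  The column marginal is exactly the independent model's,
    so planted columns are indistinguishable from background by
    conservation, while the shared state creates block correlations that
    the projection method can see.  ``coupling = 0`` reproduces the
    independent generator bit-for-bit at the same seed.

``star_phylogeny``
    A few ancestor sequences are drawn from the independent model; every
    output sequence copies a random ancestor and redraws each position
    independently with probability ``mutation_rate``.  Low rates create
    weak, uniform correlations across all columns — the phylogenetic-bias
    regime.  ``mutation_rate = 1`` reproduces the independent generator.

Mutational effects are generated as a monotone function of conservation
plus Gaussian noise, emulating datasets in which conservation predicts
functional impact.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .alignment import Alignment
from .compare import MutationalDataset, call_functional_sites
from .conservation import ConservationProfile


class GeneratorError(ValueError):
    pass


@dataclasses.dataclass
class GeneratorSpec:
    """Parameters of a synthetic-alignment generator run.

    ``conservation_profile`` may be a scalar (flat profile) or a length-n
    vector of dominant-residue frequencies in (0, 1].  ``seed`` is
    mandatory; all randomness derives from it.
    """

    kind: str
    N: int
    n: int
    seed: int
    conservation_profile: float | Sequence[float] = 0.5
    sector_positions: Sequence[int] | None = None
    coupling: float = 0.0
    n_ancestors: int = 1
    mutation_rate: float = 1.0

    def profile_vector(self) -> np.ndarray:
        p = np.asarray(self.conservation_profile, dtype=float)
        if p.ndim == 0:
            p = np.full(self.n, float(p))
        if p.shape != (self.n,):
            raise GeneratorError("profile length must equal n")
        if np.any(p <= 0) or np.any(p > 1):
            raise GeneratorError("profile values must lie in (0, 1]")
        return p

    def __post_init__(self) -> None:
        if self.kind not in {"independent", "planted_sector", "star_phylogeny"}:
            raise GeneratorError(f"unknown generator kind {self.kind!r}")
        if self.N < 1 or self.n < 1:
            raise GeneratorError("N and n must be positive")
        if self.seed is None:
            raise GeneratorError("seed is mandatory")
        if not 0.0 <= self.coupling <= 1.0:
            raise GeneratorError("coupling must be in [0, 1]")
        if self.kind == "planted_sector":
            pos = self.sector_positions
            if pos is None or len(pos) == 0:
                raise GeneratorError("planted_sector requires sector_positions")
            pos = list(pos)
            if len(set(pos)) != len(pos) or min(pos) < 0 or max(pos) >= self.n:
                raise GeneratorError("invalid or duplicate sector positions")
        if self.kind == "star_phylogeny":
            if self.n_ancestors < 1:
                raise GeneratorError("n_ancestors must be >= 1")
            if not 0.0 < self.mutation_rate <= 1.0:
                raise GeneratorError("mutation_rate must be in (0, 1]")


def heterogeneous_profile(
    n: int, seed: int, low: float = 0.05, high: float = 0.5
) -> np.ndarray:
    """A seeded heterogeneous conservation profile, uniform on [low, high].

    The default range runs from the background level (no conservation)
    to one half, the diversity regime of deep homolog alignments; it is
    also the regime in which this generator's projected column variance
    grows monotonically with conservation (see the methods note).
    """
    rng = np.random.default_rng([seed, 7])
    return rng.uniform(low, high, size=n)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    # independent child streams so that generators sharing a seed agree on
    # the draws they have in common (exact reduction at coupling 0 / rate 1)
    return {
        "dominant": np.random.default_rng([seed, 0]),
        "state": np.random.default_rng([seed, 1]),
        "cells": np.random.default_rng([seed, 2]),
        "ancestry": np.random.default_rng([seed, 3]),
    }


def _emission_tables(n: int, rng: np.random.Generator):
    """Pick a dominant residue per column and tabulate the 19 others."""
    dominant = rng.integers(0, 20, size=n)
    others = np.empty((n, 19), dtype=np.int8)
    for i in range(n):
        others[i] = [a for a in range(20) if a != dominant[i]]
    return dominant, others


def _emit(u: np.ndarray, p: np.ndarray, dominant, others) -> np.ndarray:
    """Inverse-CDF categorical emission from per-cell uniforms.

    ``u`` and ``p`` are N x n; a cell emits the column's dominant residue
    when u < p, otherwise one of the 19 alternatives, uniformly.
    """
    N, n = u.shape
    is_dom = u < p
    with np.errstate(divide="ignore", invalid="ignore"):
        alt = np.floor((u - p) / (1.0 - p) * 19).astype(int)
    alt = np.clip(alt, 0, 18)
    cols = np.broadcast_to(np.arange(n), (N, n))
    mat = np.where(is_dom, dominant[None, :], others[cols, alt])
    return mat.astype(np.int8)


def sample_independent_alignment(spec: GeneratorSpec) -> Alignment:
    """Columns i.i.d. across sequences; no correlations beyond sampling."""
    p = spec.profile_vector()
    streams = _streams(spec.seed)
    dominant, others = _emission_tables(spec.n, streams["dominant"])
    u = streams["cells"].random((spec.N, spec.n))
    mat = _emit(u, np.broadcast_to(p, (spec.N, spec.n)), dominant, others)
    return Alignment.from_matrix(mat)


def sample_sector_alignment(spec: GeneratorSpec) -> Alignment:
    """Alignment with a planted group of co-varying columns.

    The hidden state shifts the dominant-residue frequency of sector
    columns by ``+/- coupling * min(p, 1-p)`` while leaving the column
    marginal (and hence expected conservation) exactly at the independent
    model's values.
    """
    if spec.kind != "planted_sector":
        spec = dataclasses.replace(spec, kind="planted_sector")
        spec.__post_init__()
    p = spec.profile_vector()
    sector = np.asarray(sorted(spec.sector_positions), dtype=int)
    streams = _streams(spec.seed)
    dominant, others = _emission_tables(spec.n, streams["dominant"])
    # equiprobable hidden states, assigned as a random permutation of an
    # exactly balanced vector: an i.i.d. assignment leaves a global
    # state-imbalance mode that correlates the sampling noise of all
    # sector columns and confounds the conservation comparison
    half = spec.N // 2
    base = np.concatenate([np.zeros(spec.N - half, int), np.ones(half, int)])
    state = streams["state"].permutation(base)
    delta = spec.coupling * np.minimum(p, 1.0 - p)
    p_cells = np.broadcast_to(p, (spec.N, spec.n)).copy()
    sign = np.where(state == 0, 1.0, -1.0)
    p_cells[:, sector] = p[sector][None, :] + np.outer(sign, delta[sector])
    u = streams["cells"].random((spec.N, spec.n))
    mat = _emit(u, p_cells, dominant, others)
    return Alignment.from_matrix(mat)


def sample_star_phylogeny_alignment(spec: GeneratorSpec) -> Alignment:
    """Uniform global correlations via shared ancestry.

    Each sequence copies one of ``n_ancestors`` ancestor sequences and
    redraws each position with probability ``mutation_rate`` from the
    independent column distribution.
    """
    p = spec.profile_vector()
    streams = _streams(spec.seed)
    dominant, others = _emission_tables(spec.n, streams["dominant"])
    anc_u = streams["ancestry"].random((spec.n_ancestors, spec.n))
    ancestors = _emit(
        anc_u, np.broadcast_to(p, (spec.n_ancestors, spec.n)), dominant, others
    )
    which = streams["ancestry"].integers(0, spec.n_ancestors, size=spec.N)
    redraw = streams["state"].random((spec.N, spec.n)) < spec.mutation_rate
    u = streams["cells"].random((spec.N, spec.n))
    fresh = _emit(u, np.broadcast_to(p, (spec.N, spec.n)), dominant, others)
    mat = np.where(redraw, fresh, ancestors[which])
    return Alignment.from_matrix(mat.astype(np.int8))


def sample_alignment(spec: GeneratorSpec) -> Alignment:
    """Dispatch on ``spec.kind``."""
    if spec.kind == "independent":
        return sample_independent_alignment(spec)
    if spec.kind == "planted_sector":
        return sample_sector_alignment(spec)
    return sample_star_phylogeny_alignment(spec)


_LINKS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda d: d,
    "linear": lambda d: 2.0 * d,
    "sqrt": lambda d: np.sqrt(np.maximum(d, 0.0)),
}


def sample_mutational_effects(
    D: ConservationProfile,
    link: str | Callable[[np.ndarray], np.ndarray] = "identity",
    noise_sd: float = 0.25,
    functional_threshold: float | None = None,
    seed: int = 0,
) -> MutationalDataset:
    """Per-position effects as a monotone function of conservation + noise.

    ``link`` is a named monotone function ("identity", "linear", "sqrt")
    or a callable, which is checked for (non-strict) monotonicity on the
    observed conservation values.  Functional flags are set by an
    effect-threshold rule when ``functional_threshold`` is given.
    Positions are numbered 1..n.
    """
    d = np.asarray(D.D, dtype=float)
    if isinstance(link, str):
        if link not in _LINKS:
            raise GeneratorError(f"unknown link {link!r}")
        fn = _LINKS[link]
    else:
        fn = link
    grid = np.sort(d)
    vals = fn(grid)
    if np.any(np.diff(vals) < -1e-12):
        raise GeneratorError("link function must be monotone nondecreasing")
    rng = np.random.default_rng([seed, 11])
    effect = fn(d) + rng.normal(0.0, noise_sd, size=d.size)
    data = MutationalDataset(
        position=np.arange(1, d.size + 1), effect=effect
    )
    if functional_threshold is not None:
        data = call_functional_sites(
            data, "effect_threshold", functional_threshold
        )
    return data
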