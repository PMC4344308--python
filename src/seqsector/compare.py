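"""Statistical comparison of sector positions against conserved positions.

Given a per-position mutational dataset (mean mutational effect, free
energy difference, or loss-of-function substitution counts), the battery
asks whether the top-eigenvector sector is any better than an equally
sized set of most-conserved positions at predicting functional sites:

* 2x2 contingency tables (in-set vs functional) with a one-tailed Fisher
  exact test for enrichment;
* a chi-squared homogeneity test comparing the sector table against the
  conservation table;
* a two-sided Mann-Whitney U test comparing the distribution of effects
  over the two sets;
* a sweep over sector sizes reporting the Mann-Whitney p-value and the
  set overlap at each size;
* ordinary least squares of per-position phenotypes on eigenvector
  components.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conservation import ConservationProfile, top_conserved_set
from .sca import SpectralResult, top_k_positions

logger = logging.getLogger(__name__)


class ComparisonError(ValueError):
    pass


@dataclasses.dataclass
class MutationalDataset:
    """Per-position phenotypic effects with functional-site flags.

    ``position`` holds 1-based reference residue numbers; ``effect`` the
    scalar per-position effect; ``functional`` boolean flags under the
    rule recorded in ``rule``.  ``counts`` optionally carries
    (n_deleterious, n_tested) pairs for count-threshold data.
    """

    position: np.ndarray
    effect: np.ndarray
    functional: np.ndarray | None = None
    rule: dict | None = None
    counts: np.ndarray | None = None  # shape (m, 2): deleterious, tested

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=int)
        self.effect = np.asarray(self.effect, dtype=float)
        if len(np.unique(self.position)) != len(self.position):
            raise ComparisonError("positions must be unique")
        if self.effect.shape != self.position.shape:
            raise ComparisonError("effect and position lengths differ")
        if self.functional is not None:
            self.functional = np.asarray(self.functional, dtype=bool)
            if self.functional.shape != self.position.shape:
                raise ComparisonError("functional flags length mismatch")

    def effect_at(self, positions: Iterable[int]) -> np.ndarray:
        idx = {p: i for i, p in enumerate(self.position)}
        try:
            return self.effect[[idx[p] for p in positions]]
        except KeyError as exc:
            raise ComparisonError(f"position {exc.args[0]} has no effect value")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MutationalDataset":
        """Build from a table with columns ``position``, ``effect`` and
        optionally ``n_deleterious``/``n_tested`` and ``functional``."""
        counts = None
        if {"n_deleterious", "n_tested"} <= set(df.columns):
            counts = df[["n_deleterious", "n_tested"]].to_numpy(dtype=int)
        functional = None
        if "functional" in df.columns:
            functional = df["functional"].to_numpy(dtype=bool)
        return cls(
            position=df["position"].to_numpy(dtype=int),
            effect=df["effect"].to_numpy(dtype=float),
            functional=functional,
            counts=counts,
        )

    @classmethod
    def read_table(cls, path) -> "MutationalDataset":
        """Read a delimited text table (whitespace or comma separated)."""
        df = pd.read_csv(path, sep=None, engine="python")
        return cls.from_dataframe(df)


def call_functional_sites(
    data: MutationalDataset, rule: str, threshold: float
) -> MutationalDataset:
    """Flag functional sites under an explicit rule.

    ``effect_threshold``: functional iff |effect| >= threshold (e.g. a
    free-energy shift of at least 1 kcal/mol).  ``count_threshold``:
    functional iff the loss-of-function substitution count >= threshold
    (e.g. at least 8 of the tested substitutions); uses ``counts`` when
    present, else the effect value is interpreted as the count.
    """
    if rule == "effect_threshold":
        functional = np.abs(data.effect) >= threshold
    elif rule == "count_threshold":
        counts = (
            data.counts[:, 0] if data.counts is not None else data.effect
        )
        functional = np.asarray(counts) >= threshold
    else:
        raise ComparisonError(f"unknown functional-site rule {rule!r}")
    return dataclasses.replace(
        data,
        functional=functional,
        rule={"rule": rule, "threshold": threshold},
    )


@dataclasses.dataclass
class ContingencyTable:
    """2x2 table: rows in-set / not-in-set, columns functional / not."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (2, 2):
            raise ComparisonError("contingency table must be 2x2")
        if np.any(self.counts < 0):
            raise ComparisonError("contingency counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def in_set_row(self) -> np.ndarray:
        return self.counts[0]


def contingency(
    set_a: Sequence[int],
    data: MutationalDataset,
    universe: Sequence[int] | None = None,
) -> ContingencyTable:
    """Cross-tabulate set membership against functional flags.

    ``universe`` defaults to all scored positions; ``set_a`` must lie
    inside it.
    """
    if data.functional is None:
        raise ComparisonError("functional flags not set; call_functional_sites first")
    if universe is None:
        universe = list(data.position)
    universe = list(universe)
    scored = set(int(p) for p in data.position)
    missing = [p for p in set_a if p not in scored]
    if missing:
        raise ComparisonError(f"set contains unscored positions {missing}")
    if not set(set_a) <= set(universe):
        raise ComparisonError("set_a must be a subset of the universe")
    func = {int(p): bool(v) for p, v in zip(data.position, data.functional)}
    sa = set(int(p) for p in set_a)
    counts = np.zeros((2, 2), dtype=int)
    for p in universe:
        row = 0 if p in sa else 1
        col = 0 if func[int(p)] else 1
        counts[row, col] += 1
    return ContingencyTable(counts=counts)


def fisher_one_tailed(table: ContingencyTable) -> float:
    """One-tailed Fisher exact p-value for enrichment.

    Exact hypergeometric upper tail: the probability that the in-set
    functional count is at least the observed one, given the margins.
    Degenerate margins (an empty row or column) give p = 1 with a warning.
    """
    a = int(table.counts[0, 0])
    K = int(table.counts[:, 0].sum())  # functional total
    n_draw = int(table.counts[0].sum())  # set size
    M = table.total
    if K == 0 or n_draw == 0 or K == M or n_draw == M:
        logger.warning("degenerate contingency margins; Fisher p set to 1")
        return 1.0
    # sum of hypergeometric pmf over the upper tail
    p = float(stats.hypergeom.sf(a - 1, M, K, n_draw))
    return min(p, 1.0)


def chi2_compare_tables(
    table_a: ContingencyTable,
    table_b: ContingencyTable,
    yates: bool = False,
) -> float:
    """Pearson chi-squared homogeneity test between two tables' in-set rows.

    The two tables share their universe, so only the in-set (functional,
    not-functional) rows are compared: a 2x2 layout with rows = {set A,
    set B}, 1 degree of freedom.  No continuity correction by default
    (``yates`` enables it).  Returns NaN with a warning when an expected
    cell is zero.
    """
    layout = np.vstack([table_a.in_set_row, table_b.in_set_row])
    row_tot = layout.sum(axis=1, keepdims=True)
    col_tot = layout.sum(axis=0, keepdims=True)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        logger.warning("zero expected cell; chi-squared p undefined")
        return float("nan")
    if np.array_equal(layout[0], layout[1]):
        return 1.0  # identical rows: statistic exactly 0
    res = stats.chi2_contingency(layout, correction=yates)
    return float(res.pvalue)


def mannwhitney_effects(
    data: MutationalDataset,
    set_a: Sequence[int],
    set_b: Sequence[int],
    exact_limit: int = 8,
) -> float:
    """Two-sided Mann-Whitney U p-value comparing effect distributions.

    Exact enumeration when both samples have at most ``exact_limit``
    members and no ties are present; otherwise the normal approximation
    with tie correction.  Sets are used as given — they may overlap, as
    the sector and the conserved set typically do.
    """
    if len(set_a) == 0 or len(set_b) == 0:
        raise ComparisonError("both position sets must be nonempty")
    x = data.effect_at(set_a)
    y = data.effect_at(set_b)
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) <= exact_limit and len(y) <= exact_limit and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def sweep_sector_size(
    spec: SpectralResult,
    D: ConservationProfile,
    data: MutationalDataset,
    sizes: Sequence[int],
    column_to_position: Sequence[int | None] | None = None,
) -> pd.DataFrame:
    """Mann-Whitney comparison of sector vs conserved sets over sizes.

    For each size ``k``, takes the top-k eigenvector columns and the top-k
    conserved columns, maps them to residue numbers via
    ``column_to_position`` (identity + 1 if omitted), and reports the
    two-sided Mann-Whitney p on the effect distributions plus the overlap
    fraction |A intersect B| / k.
    """
    n = len(D)

    def to_positions(cols: Sequence[int]) -> list[int]:
        if column_to_position is None:
            return [c + 1 for c in cols]
        mapped = [column_to_position[c] for c in cols]
        return [int(p) for p in mapped if p is not None]

    records = []
    for k in sizes:
        if not 1 <= k <= n:
            raise ComparisonError(f"size {k} outside [1, {n}]")
        cols_sector = top_k_positions(spec, k)
        cols_cons = top_conserved_set(D, k)
        pos_sector = to_positions(cols_sector)
        pos_cons = to_positions(cols_cons)
        scored = set(int(p) for p in data.position)
        pos_sector = [p for p in pos_sector if p in scored]
        pos_cons = [p for p in pos_cons if p in scored]
        if not pos_sector or not pos_cons:
            raise ComparisonError(f"size {k}: no scored positions in a set")
        p = mannwhitney_effects(data, pos_sector, pos_cons)
        overlap = len(set(cols_sector) & set(cols_cons)) / k
        records.append({"size": k, "p_mannwhitney": p, "overlap": overlap})
    return pd.DataFrame.from_records(records)


@dataclasses.dataclass
class EigenvectorRegression:
    """OLS fit of per-position phenotypes on eigenvector components."""

    coefficients: np.ndarray  # intercept first
    fitted: np.ndarray
    r_squared: float
    n_modes: int


def regress_phenotypes_on_eigenvectors(
    data: MutationalDataset,
    spec: SpectralResult,
    m: int,
    column_to_position: Sequence[int | None] | None = None,
) -> EigenvectorRegression:
    """Least-squares fit of phenotype on the top-m eigenvector components.

    The design holds, for each scored position, the components of the top
    ``m`` eigenvectors at that position plus an intercept.  ``m = 0``
    fits the mean alone (R^2 = 0).
    """
    n = spec.eigenvectors.shape[0]
    if column_to_position is None:
        col_of_pos = {c + 1: c for c in range(n)}
    else:
        col_of_pos = {
            int(p): c for c, p in enumerate(column_to_position) if p is not None
        }
    rows = [
        (i, col_of_pos[int(p)])
        for i, p in enumerate(data.position)
        if int(p) in col_of_pos
    ]
    if len(rows) <= m + 1:
        raise ComparisonError(
            f"underdetermined regression: {len(rows)} positions for {m} modes"
        )
    y = data.effect[[i for i, _ in rows]]
    cols = [c for _, c in rows]
    X = np.column_stack(
        [np.ones(len(rows))]
        + [spec.eigenvectors[cols, r] for r in range(m)]
    )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if m == 0:
        r2 = 0.0
    return EigenvectorRegression(
        coefficients=beta, fitted=fitted, r_squared=r2, n_modes=m
    )
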