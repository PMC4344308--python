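"""Multiple sequence alignment container, FASTA I/O and preprocessing.

An alignment is held as an ``N x n`` character matrix over a 21-symbol
alphabet: the 20 standard amino acids plus the gap symbol ``-``.  Input is
normalised aggressively (case folding, ``.`` -> ``-``, ambiguity codes to
gap) so that every downstream frequency computation can assume the fixed
alphabet.  Internal coordinates are 0-based; reports use 1-based residue
numbers of a designated reference sequence.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: str = AMINO_ACIDS + GAP
N_SYMBOLS: int = len(ALPHABET)  # 21
GAP_INDEX: int = ALPHABET.index(GAP)

# Letters that are legal in sequence files but have no slot in the
# 20-letter frequency model; they are mapped to gap on input.
_AMBIGUOUS = set("BJOUXZ")

_SYMBOL_TO_INDEX = {s: i for i, s in enumerate(ALPHABET)}


class AlignmentError(ValueError):
    """Raised for malformed or inconsistent alignments."""


def _normalize_row(seq: str, record_id: str) -> str:
    out = []
    for ch in seq.upper():
        if ch == "." or ch == "-":
            out.append(GAP)
        elif ch in _AMBIGUOUS:
            out.append(GAP)
        elif ch in _SYMBOL_TO_INDEX:
            out.append(ch)
        else:
            raise AlignmentError(
                f"record {record_id!r}: unrecognised symbol {ch!r}"
            )
    return "".join(out)


@dataclasses.dataclass
class Alignment:
    """An aligned set of protein sequences over the 21-symbol alphabet.

    Parameters
    ----------
    ids
        Sequence identifiers, in file order.
    rows
        Sequences, all of equal length, already normalised.
    reference_id
        Optional identifier of the seed/reference sequence used for
        residue numbering.
    column_origin
        For a column-filtered alignment, the original index of each
        retained column.  ``None`` for an unfiltered alignment.
    """

    ids: list[str]
    rows: list[str]
    reference_id: str | None = None
    column_origin: list[int] | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if not self.rows:
            raise AlignmentError("alignment has no sequences")
        n = len(self.rows[0])
        if n < 1:
            raise AlignmentError("alignment has zero columns")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise AlignmentError(
                    f"record {rid!r} has length {len(row)}, expected {n}"
                )
            bad = set(row) - set(ALPHABET)
            if bad:
                raise AlignmentError(
                    f"record {rid!r} contains invalid symbols {sorted(bad)}"
                )
        if self.column_origin is not None:
            co = self.column_origin
            if len(co) != n:
                raise AlignmentError("column_origin length mismatch")
            if any(b <= a for a, b in zip(co, co[1:])):
                raise AlignmentError("column_origin must be strictly increasing")

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def to_matrix(self) -> np.ndarray:
        """Return the alignment as an ``N x n`` array of symbol indices."""
        return np.array(
            [[_SYMBOL_TO_INDEX[c] for c in row] for row in self.rows],
            dtype=np.int8,
        )

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows)

    @classmethod
    def from_matrix(
        cls,
        mat: np.ndarray,
        ids: Sequence[str] | None = None,
        reference_id: str | None = None,
    ) -> "Alignment":
        """Build an Alignment from an integer symbol-index matrix."""
        mat = np.asarray(mat)
        rows = ["".join(ALPHABET[int(v)] for v in r) for r in mat]
        if ids is None:
            ids = [f"seq{k}" for k in range(len(rows))]
        return cls(ids=list(ids), rows=rows, reference_id=reference_id)


def read_fasta_alignment(path: str | Path, reference_id: str | None = None) -> Alignment:
    """Read an aligned FASTA file.

    Lowercase letters are uppercased; ``.`` and ``-`` both become the gap
    symbol; ambiguity codes (B, J, O, U, X, Z) map to gap.  Raises
    :class:`AlignmentError` on ragged input, naming the offending record.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    ids = [r.id for r in records]
    rows = [_normalize_row(str(r.seq), r.id) for r in records]
    n = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != n:
            raise AlignmentError(
                f"ragged alignment: record {rid!r} has length {len(row)}, "
                f"expected {n}"
            )
    return Alignment(ids=ids, rows=rows, reference_id=reference_id)


def write_fasta_alignment(aln: Alignment, path: str | Path) -> None:
    """Write the alignment as multi-record FASTA (gap written as ``-``)."""
    records = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(aln.ids, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def gap_fractions(aln: Alignment) -> np.ndarray:
    """Per-column fraction of gap symbols."""
    mat = aln.to_matrix()
    return (mat == GAP_INDEX).mean(axis=0)


def filter_gap_columns(aln: Alignment, max_gap_fraction: float = 0.4) -> Alignment:
    """Remove columns with gap fraction at or above ``max_gap_fraction``.

    Columns with 40% or more gaps (default) are treated as insert states
    and dropped; exactly the columns with gap fraction strictly below the
    threshold are retained.  ``column_origin`` records the retained original
    indices (composed through prior filtering if present).
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must be in [0, 1]")
    frac = gap_fractions(aln)
    keep = np.flatnonzero(frac < max_gap_fraction)
    if keep.size == 0:
        raise AlignmentError(
            "gap filtering removed every column "
            f"(threshold {max_gap_fraction})"
        )
    prior = aln.column_origin
    origin = [int(j) if prior is None else prior[int(j)] for j in keep]
    rows = ["".join(row[j] for j in keep) for row in aln.rows]
    return Alignment(
        ids=list(aln.ids),
        rows=rows,
        reference_id=aln.reference_id,
        column_origin=origin,
    )


def map_columns_to_reference(aln: Alignment, ref_id: str) -> list[int | None]:
    """Map each alignment column to a 1-based reference residue number.

    Column ``j`` maps to the count of non-gap reference symbols in columns
    ``0..j`` when the reference is non-gap at ``j``, else ``None``.  The
    mapping is injective where defined.
    """
    try:
        k = aln.ids.index(ref_id)
    except ValueError:
        raise AlignmentError(f"reference id {ref_id!r} not in alignment") from None
    ref = aln.rows[k]
    mapping: list[int | None] = []
    count = 0
    for ch in ref:
        if ch == GAP:
            mapping.append(None)
        else:
            count += 1
            mapping.append(count)
    return mapping
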