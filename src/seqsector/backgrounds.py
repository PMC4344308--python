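"""Background amino-acid frequency tables.

Relative-entropy conservation and the SCA positional weights both compare
column frequencies against the frequency with which each amino acid occurs
in a large protein database.  The default table here is the
Robinson–Robinson database-average frequencies, a standard choice for such
backgrounds.  A uniform background (0.05 per amino acid) is provided for
self-contained numeric tests, and any user table can be loaded from a YAML
or two-column text file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .alignment import AMINO_ACIDS

# Robinson & Robinson database-average amino-acid frequencies.
ROBINSON_FREQUENCIES: dict[str, float] = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}


def uniform_background() -> np.ndarray:
    """Uniform background: each of the 20 amino acids at 0.05."""
    return np.full(20, 0.05)


def default_background() -> np.ndarray:
    """Database-average background over the 20 amino acids, normalised."""
    q = np.array([ROBINSON_FREQUENCIES[a] for a in AMINO_ACIDS])
    return q / q.sum()


def load_background(path: str | Path) -> np.ndarray:
    """Load a per-amino-acid background from a YAML mapping file.

    The file maps one-letter amino-acid codes to frequencies; values are
    renormalised to sum to 1.  Missing amino acids are an error.
    """
    with open(path) as fh:
        table = yaml.safe_load(fh)
    if not isinstance(table, dict):
        raise ValueError(f"background file {path} must be a mapping")
    missing = [a for a in AMINO_ACIDS if a not in table]
    if missing:
        raise ValueError(f"background file {path} missing amino acids {missing}")
    q = np.array([float(table[a]) for a in AMINO_ACIDS])
    if np.any(q < 0) or q.sum() <= 0:
        raise ValueError("background frequencies must be nonnegative, sum > 0")
    return q / q.sum()
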