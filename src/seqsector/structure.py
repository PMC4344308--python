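"""Structural "touching" analysis and conservation versus burial depth.

For domain-insertion experiments, the perturbation acts at the peptide
bond preceding the insertion residue.  A residue is said to touch an
insertion site when any of its atoms lies within a fixed radius (default
4 Angstrom) of any of the four peptide-bond atoms: C and O of the
preceding residue, N and CA of the insertion residue.  The module also
relates per-residue conservation to distance from the protein's
geometric center, since conserved residues tend to cluster in the core.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.PDB import PDBParser
from scipy import stats

logger = logging.getLogger(__name__)

# atoms defining the peptide bond broken by an insertion before residue i:
# carbonyl C and O of residue i-1, amide N and CA of residue i
PEPTIDE_BOND_ATOMS_PREV = ("C", "O")
PEPTIDE_BOND_ATOMS_NEXT = ("N", "CA")


class StructureError(ValueError):
    pass


@dataclasses.dataclass
class Residue:
    number: int
    chain: str
    name: str
    atoms: dict[str, np.ndarray]  # atom name -> xyz (Angstrom)

    def centroid(self) -> np.ndarray:
        return np.mean(list(self.atoms.values()), axis=0)


@dataclasses.dataclass
class StructureModel:
    """Ordered heavy-atom residues of one chain of one model."""

    residues: list[Residue]

    def __post_init__(self) -> None:
        numbers = [r.number for r in self.residues]
        if len(set(numbers)) != len(numbers):
            raise StructureError("duplicate residue numbers in chain")
        self._by_number = {r.number: r for r in self.residues}

    def residue(self, number: int) -> Residue:
        try:
            return self._by_number[number]
        except KeyError:
            raise StructureError(f"residue {number} not in structure") from None

    def __contains__(self, number: int) -> bool:
        return number in self._by_number

    def all_atom_coords(self) -> np.ndarray:
        return np.vstack([
            xyz for r in self.residues for xyz in r.atoms.values()
        ])


def read_structure(path: str | Path, chain: str | None = None) -> StructureModel:
    """Parse a PDB file into a heavy-atom structure model.

    Uses the first model; hydrogen atoms are dropped; alternate locations
    resolve to the highest-occupancy conformer.  ``chain`` defaults to
    the first chain in the model.
    """
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("s", str(path))
    except Exception as exc:
        raise StructureError(f"could not parse PDB file {path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise StructureError(f"no models in {path}")
    model = models[0]
    chains = {c.id: c for c in model}
    if chain is None:
        if not chains:
            raise StructureError(f"no chains in {path}")
        chain = next(iter(chains))
    if chain not in chains:
        raise StructureError(
            f"chain {chain!r} not in {path}; available: {sorted(chains)}"
        )
    residues = []
    for res in chains[chain]:
        if res.id[0] != " ":  # skip heteroatoms and waters
            continue
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            # Biopython keeps the highest-occupancy altloc as the
            # selected child of a disordered atom
            if atom.element in ("H", "D"):
                continue
            atoms[atom.get_name()] = np.asarray(atom.coord, dtype=float)
        if atoms:
            residues.append(
                Residue(
                    number=res.id[1],
                    chain=chain,
                    name=res.get_resname(),
                    atoms=atoms,
                )
            )
    if not residues:
        raise StructureError(f"no residues parsed from chain {chain!r}")
    return StructureModel(residues=residues)


def _peptide_bond_centers(
    s: StructureModel, insertion_residue: int
) -> np.ndarray:
    prev_num = insertion_residue - 1
    if prev_num not in s or insertion_residue not in s:
        raise StructureError(
            f"insertion at residue {insertion_residue} needs residues "
            f"{prev_num} and {insertion_residue} present (no preceding "
            "peptide bond at the chain start)"
        )
    prev = s.residue(prev_num)
    curr = s.residue(insertion_residue)
    centers = []
    for name in PEPTIDE_BOND_ATOMS_PREV:
        if name in prev.atoms:
            centers.append(prev.atoms[name])
    for name in PEPTIDE_BOND_ATOMS_NEXT:
        if name in curr.atoms:
            centers.append(curr.atoms[name])
    if not centers:
        raise StructureError(
            f"no peptide-bond atoms found around residue {insertion_residue}"
        )
    return np.vstack(centers)


def touching_residues(
    s: StructureModel, insertion_residue: int, cutoff: float = 4.0
) -> set[int]:
    """Residues with any atom within ``cutoff`` of the peptide-bond atoms.

    Spheres of radius ``cutoff`` are centered on the four atoms of the
    peptide bond preceding ``insertion_residue``; membership is inclusive
    (distance <= cutoff).
    """
    if cutoff <= 0:
        raise StructureError("cutoff must be positive")
    centers = _peptide_bond_centers(s, insertion_residue)
    touching = set()
    for res in s.residues:
        coords = np.vstack(list(res.atoms.values()))
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        if np.any(d2 <= cutoff**2):
            touching.add(res.number)
    return touching


def sector_touch_counts(
    sector_residues: Sequence[int],
    insertion_sites: Sequence[int],
    s: StructureModel,
    cutoff: float = 4.0,
) -> tuple[int, dict[int, bool]]:
    """How many insertion sites the sector touches.

    A site is touched when at least one sector residue lies within the
    touching set of that site.  Returns the count and a per-site map.
    """
    sector = set(int(r) for r in sector_residues)
    detail = {}
    for site in insertion_sites:
        detail[int(site)] = bool(sector & touching_residues(s, site, cutoff))
    return sum(detail.values()), detail


def conservation_vs_center_distance(
    s: StructureModel,
    D: Mapping[int, float],
    use_calpha: bool = False,
) -> dict:
    """Per-residue distance from the geometric center versus conservation.

    The center is the unweighted mean over all heavy atoms; each mapped
    residue contributes (distance of its heavy-atom centroid, D).
    Residues without a conservation value are skipped with a warning.
    Returns the paired arrays and the Spearman rank correlation.
    """
    center = s.all_atom_coords().mean(axis=0)
    pairs = []
    skipped = 0
    for res in s.residues:
        if res.number not in D:
            skipped += 1
            continue
        if use_calpha and "CA" in res.atoms:
            point = res.atoms["CA"]
        else:
            point = res.centroid()
        pairs.append((res.number, float(np.linalg.norm(point - center)), D[res.number]))
    if skipped:
        logger.warning("%d residue(s) without conservation value skipped", skipped)
    if not pairs:
        raise StructureError("no residues with conservation values")
    numbers, dist, cons = zip(*pairs)
    if len(pairs) >= 3:
        rho = stats.spearmanr(dist, cons)
        rho_stat, rho_p = float(rho.statistic), float(rho.pvalue)
    else:
        logger.warning("fewer than 3 residues; Spearman correlation undefined")
        rho_stat, rho_p = float("nan"), float("nan")
    return {
        "residue": np.asarray(numbers),
        "distance": np.asarray(dist),
        "conservation": np.asarray(cons),
        "spearman_rho": rho_stat,
        "spearman_p": rho_p,
        "center": center,
    }
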