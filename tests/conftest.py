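import numpy as np
import pytest

from seqsector import Alignment, backgrounds


@pytest.fixture
def uniform_q():
    return backgrounds.uniform_background()


@pytest.fixture
def tiny_alignment():
    return Alignment(
        ids=["s1", "s2", "s3", "s4"],
        rows=["ACDE", "ACDF", "AC-E", "AGDE"],
        reference_id="s1",
    )


@pytest.fixture
def random_alignment_factory():
    """Seeded random alignments over the full 21-symbol alphabet."""

    def make(N, n, seed, gap_prob=0.1):
        rng = np.random.default_rng(seed)
        mat = rng.integers(0, 20, size=(N, n))
        gaps = rng.random((N, n)) < gap_prob
        mat[gaps] = 20
        return Alignment.from_matrix(mat)

    return make


def write_pdb(path, atoms):
    """Write a minimal PDB file from (serial, name, resname, chain,
    resseq, x, y, z, occupancy, altloc, element) tuples."""
    lines = []
    for (serial, name, resname, chain, resseq, x, y, z, occ, alt, elem) in atoms:
        lines.append(
            f"ATOM  {serial:5d} {name:<4s}{alt:1s}{resname:<3s} {chain:1s}"
            f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {elem:>2s}"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


def make_backbone_atoms(positions, chain="A", start_res=1):
    """Backbone-only residues (N, CA, C, O) at given CA positions; the
    four atoms of each residue are offset slightly from the CA."""
    atoms = []
    serial = 1
    offsets = {"N": (-0.8, 0.0, 0.0), "CA": (0.0, 0.0, 0.0),
               "C": (0.8, 0.0, 0.0), "O": (0.8, 0.8, 0.0)}
    for i, (x, y, z) in enumerate(positions):
        for name, (dx, dy, dz) in offsets.items():
            atoms.append((serial, name, "ALA", chain, start_res + i,
                          x + dx, y + dy, z + dz, 1.0, " ", name[0]))
            serial += 1
    return atoms


@pytest.fixture
def pdb_writer():
    return write_pdb


@pytest.fixture
def backbone_atoms():
    return make_backbone_atoms
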