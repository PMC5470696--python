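import numpy as np
import pytest

from predsav.structure import AtomRecord, ProteinStructure, Residue
from predsav.fixtures import generate_base_features, generate_structure


def make_residue(seq_index, coords, aa="A", chain="A", elements=None, names=None):
    """Residue from raw coordinates (one heavy atom per row)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = elements or ["C"] * n
    names = names or [f"C{i}" for i in range(n)]
    atoms = [
        AtomRecord(name=names[i], element=elements[i], coords=coords[i])
        for i in range(n)
    ]
    return Residue(
        chain_id=chain, seq_index=seq_index, auth_number=str(seq_index + 1),
        aa=aa, atoms=atoms,
    )


def point_structure(points, structure_id="points"):
    """Structure with one single-atom residue per point."""
    residues = [make_residue(i, [p]) for i, p in enumerate(np.atleast_2d(points))]
    return ProteinStructure(structure_id=structure_id, residues=residues)


@pytest.fixture(scope="session")
def helix30():
    return generate_structure(30, seed=7)


@pytest.fixture(scope="session")
def helix30_features(helix30):
    return generate_base_features(helix30, n_features=6, seed=11)


# --- hand-written PDB fragment: ALA-GLY-SER plus water/ligand/hydrogens ----

PDB_FRAGMENT = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB AALA A   1       2.000  -0.700   1.200  0.60  0.00           C
ATOM      6  CB BALA A   1       2.100  -0.800   1.100  0.40  0.00           C
ATOM      7  HA  ALA A   1       1.800  -0.500  -0.900  1.00  0.00           H
ATOM      8  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      9  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM     10  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM     11  O   GLY A   2       6.030   1.580   0.000  1.00  0.00           O
ATOM     12  N   SER A   3       6.230   3.810   0.000  1.00  0.00           N
ATOM     13  CA  SER A   3       7.686   3.780   0.000  1.00  0.00           C
ATOM     14  C   SER A   3       8.250   5.196   0.000  1.00  0.00           C
ATOM     15  O   SER A   3       7.500   6.180   0.000  1.00  0.00           O
ATOM     16  OG  SER A   3       8.200   3.000   1.100  1.00  0.00           O
HETATM   17  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
HETATM   18  C1  LIG A 201      12.000  12.000  12.000  1.00  0.00           C
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    path = tmp_path / "fragment.pdb"
    path.write_text(PDB_FRAGMENT)
    return path
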