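"""Chain-of-residues structure model parsed from PDB files.

Every structural feature downstream (Euclidean/Voronoi neighborhoods, the
residue-contact network, the Delaunay four-body potential) is computed from
the heavy-atom coordinates held here.  Residues are addressed by
``seq_index``, a 0-based contiguous position along the parsed chain; the
author numbering from the PDB file (which may contain gaps and insertion
codes) is retained only for reporting and for resolving variant tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

#: Three-letter to one-letter codes for the 20 canonical amino acids.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Selenomethionine is parsed as methionine; other modified residues are dropped.
NONSTANDARD_MAP = {"MSE": "M"}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_HYDROGEN_ELEMENTS = {"H", "D"}


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: label, element and 3-D position in Å."""

    name: str
    element: str
    coords: np.ndarray
    altloc: str = ""

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGEN_ELEMENTS


@dataclass
class Residue:
    """One amino acid residue with its (heavy) atoms.

    ``seq_index`` is the 0-based position along the parsed chain;
    ``auth_number`` is the author residue number plus insertion code as
    printed in the PDB file (e.g. ``"52"`` or ``"52A"``).
    """

    chain_id: str
    seq_index: int
    auth_number: str
    aa: str
    atoms: list = field(default_factory=list)

    def __post_init__(self):
        if self.aa not in AMINO_ACIDS:
            raise ValueError(f"residue {self.auth_number}: {self.aa!r} is not a canonical amino acid")

    def heavy_atoms(self) -> list:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        """Heavy-atom coordinates as an (n, 3) array."""
        atoms = self.heavy_atoms()
        if not atoms:
            raise ValueError(f"residue {self.auth_number} has no heavy atoms")
        return np.array([a.coords for a in atoms], dtype=float)


@dataclass
class ProteinStructure:
    """An ordered single-chain list of residues."""

    structure_id: str
    residues: list = field(default_factory=list)

    def __post_init__(self):
        for i, r in enumerate(self.residues):
            if r.seq_index != i:
                raise ValueError("seq_index values must be contiguous 0..len-1")
        chains = {r.chain_id for r in self.residues}
        if len(chains) > 1:
            raise ValueError(f"residues span multiple chains: {sorted(chains)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def centers(self) -> np.ndarray:
        """Heavy-atom centroid of every residue, shape (n_residues, 3)."""
        return np.array([residue_center(r) for r in self.residues])

    def find_by_auth_number(self, auth_number: str) -> Residue:
        for r in self.residues:
            if r.auth_number == str(auth_number).strip():
                return r
        raise KeyError(
            f"no residue with author number {auth_number!r} in {self.structure_id}"
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-residue summary table (one row per residue)."""
        rows = []
        for r in self.residues:
            cx, cy, cz = residue_center(r)
            rows.append(
                dict(
                    structure_id=self.structure_id,
                    chain=r.chain_id,
                    seq_index=r.seq_index,
                    auth_number=r.auth_number,
                    aa=r.aa,
                    n_heavy_atoms=len(r.heavy_atoms()),
                    center_x=cx, center_y=cy, center_z=cz,
                )
            )
        return pd.DataFrame(rows)


def _one_letter(resname: str):
    resname = resname.strip().upper()
    if resname in THREE_TO_ONE:
        return THREE_TO_ONE[resname]
    return NONSTANDARD_MAP.get(resname)


def read_structure(path, chain_id: str, structure_id: str | None = None) -> ProteinStructure:
    """Parse one chain of a PDB file into a :class:`ProteinStructure`.

    Only standard amino acid residues are kept (MSE is read as methionine);
    hydrogens are dropped and, for alternate locations, the first-listed
    altloc of each atom name is kept.  Multi-model files use the first model.

    Parameters
    ----------
    path : str or Path
        PDB file to read.
    chain_id : str
        Chain identifier to extract.
    structure_id : str, optional
        Identifier for the returned structure; defaults to ``<stem>_<chain>``.

    Raises
    ------
    KeyError
        If the chain is absent (the message lists the available chains).
    ValueError
        If the chain contains no standard amino acid residues.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models found")
    available = [c.id for c in model]
    if chain_id not in [c.id for c in model]:
        raise KeyError(
            f"chain {chain_id!r} not found in {path}; available chains: {available}"
        )
    chain = model[chain_id]

    if structure_id is None:
        from pathlib import Path as _P

        structure_id = f"{_P(str(path)).stem}_{chain_id}"

    residues = []
    for res in chain:
        hetflag, resseq, icode = res.id
        aa = _one_letter(res.get_resname())
        if hetflag.strip() and res.get_resname() not in NONSTANDARD_MAP:
            continue  # water, ligands and other HETATM groups
        if aa is None:
            warnings.warn(
                f"dropping nonstandard residue {res.get_resname()} "
                f"{resseq}{icode.strip()} in chain {chain_id}"
            )
            continue
        atoms = []
        seen_names = set()
        for atom in res.get_unpacked_list():
            element = (atom.element or "").strip()
            if element.upper() in _HYDROGEN_ELEMENTS:
                continue
            if atom.get_name() in seen_names:  # keep first-listed altloc only
                continue
            seen_names.add(atom.get_name())
            atoms.append(
                AtomRecord(
                    name=atom.get_name(),
                    element=element or atom.get_name()[0],
                    coords=np.asarray(atom.get_coord(), dtype=float),
                    altloc=atom.get_altloc().strip(),
                )
            )
        if not atoms:
            warnings.warn(f"dropping residue {resseq}{icode.strip()}: no heavy atoms")
            continue
        auth = f"{resseq}{icode.strip()}"
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=len(residues),
                auth_number=auth,
                aa=aa,
                atoms=atoms,
            )
        )
    if not residues:
        raise ValueError(f"chain {chain_id!r} of {path} contains no standard residues")
    return ProteinStructure(structure_id=structure_id, residues=residues)


def residue_center(r: Residue, mode: str = "centroid") -> np.ndarray:
    """Representative point of a residue.

    ``mode="centroid"`` (default) is the unweighted mean of the heavy-atom
    coordinates; ``mode="ca"`` uses the alpha-carbon position instead.
    """
    if mode == "centroid":
        return r.heavy_coords().mean(axis=0)
    if mode == "ca":
        for a in r.atoms:
            if a.name == "CA" and a.is_heavy:
                return a.coords.copy()
        raise ValueError(f"residue {r.auth_number} has no CA atom")
    raise ValueError(f"unknown center mode {mode!r}")


def min_heavy_atom_distance(r: Residue, n: Residue) -> float:
    """Minimum Euclidean distance (Å) over all heavy-atom pairs of two residues."""
    return float(cdist(r.heavy_coords(), n.heavy_coords()).min())


_ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def write_pdb(s: ProteinStructure, path) -> None:
    """Write the structure as minimal fixed-width ATOM records (one chain,
    sequential serial numbers); round-trips through :func:`read_structure`."""
    with open(path, "w") as fh:
        serial = 1
        for r in s.residues:
            resname = _ONE_TO_THREE[r.aa]
            try:
                resseq = int(r.auth_number)
                icode = " "
            except ValueError:
                resseq = int(r.auth_number[:-1])
                icode = r.auth_number[-1]
            for a in r.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                x, y, z = a.coords
                fh.write(
                    f"ATOM  {serial:5d} {name}{a.altloc or ' '}{resname} "
                    f"{r.chain_id}{resseq:4d}{icode}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")
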