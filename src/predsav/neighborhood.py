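"""Sequence, Euclidean and Voronoi neighborhood feature encoding.

A variant at residue ``r`` is described by three blocks built from a
per-residue base feature table (117 columns by default, standing in for the
outputs of sequence/structure predictors such as PSSM, dScore, DSSP or
NACCESS scores):

* **sequence window** — the base rows at offsets −(w−1)/2 … +(w−1)/2 around
  ``r`` along the chain (window 11 by default; out-of-chain positions are
  zero-filled), giving 11·B values;
* **Euclidean neighborhood** — for each base feature, the sum of that
  feature over all residues whose minimum heavy-atom distance to ``r`` is at
  most 5 Å, giving B values;
* **Voronoi neighborhood** — the same sum over residues sharing at least one
  Voronoi facet (equivalently, a Delaunay edge in the all-heavy-atom
  tessellation) with ``r``, giving B more values.

With B = 117 and window 11 this yields the 1521-dimensional variant vector
(1287 sequence + 117 Euclidean + 117 Voronoi features).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree, Delaunay
from scipy.spatial import QhullError

from predsav.structure import ProteinStructure

DEFAULT_RADIUS = 5.0
DEFAULT_WINDOW = 11


@dataclass
class BaseFeatureTable:
    """Per-residue scores: one row per residue, one named numeric column per feature.

    Rows are aligned to ``ProteinStructure.seq_index``.
    """

    feature_names: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D residues x features matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{len(self.feature_names)} names but {self.values.shape[1]} columns"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("base feature table contains non-finite values")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BaseFeatureTable":
        """Build from a DataFrame, ignoring the identifier columns
        (``chain``, ``auth_number``, ``aa``, ``seq_index``) if present."""
        meta = [c for c in ("chain", "auth_number", "aa", "seq_index") if c in df.columns]
        data = df.drop(columns=meta)
        return cls(feature_names=list(data.columns), values=data.to_numpy(dtype=float))

    @classmethod
    def read_tsv(cls, path) -> "BaseFeatureTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self, structure: ProteinStructure | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        if structure is not None:
            meta = pd.DataFrame(
                {
                    "chain": [r.chain_id for r in structure.residues],
                    "auth_number": [r.auth_number for r in structure.residues],
                    "aa": [r.aa for r in structure.residues],
                }
            )
            df = pd.concat([meta, df], axis=1)
        return df


@dataclass(frozen=True)
class NeighborSet:
    """Neighbors of one residue under either neighborhood definition."""

    center: int
    neighbors: frozenset
    kind: str  # "euclidean" | "voronoi"

    def __post_init__(self):
        if self.center in self.neighbors:
            raise ValueError("center must not be its own neighbor")


@dataclass
class EncodedVariant:
    """The encoded feature vector of one variant with its block provenance."""

    names: list
    vector: np.ndarray
    provenance: list  # block label per entry: "seq[+k]" | "euclidean" | "voronoi"

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        if not (len(self.names) == self.vector.size == len(self.provenance)):
            raise ValueError("names, vector and provenance must have equal length")


# ---------------------------------------------------------------------------
# neighbor relations


def _atom_table(s: ProteinStructure):
    """All heavy-atom coordinates plus the residue index of each atom."""
    coords, owner = [], []
    for r in s.residues:
        hc = r.heavy_coords()
        coords.append(hc)
        owner.extend([r.seq_index] * len(hc))
    return np.vstack(coords), np.asarray(owner)


def euclidean_adjacency(s: ProteinStructure, radius: float = DEFAULT_RADIUS) -> dict:
    """Map seq_index -> set of residues within ``radius`` Å by minimum
    heavy-atom distance (computed once for the whole structure)."""
    coords, owner = _atom_table(s)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=radius, output_type="ndarray")
    adj = {r.seq_index: set() for r in s.residues}
    if len(pairs):
        ri, rj = owner[pairs[:, 0]], owner[pairs[:, 1]]
        for a, b in zip(ri, rj):
            if a != b:
                adj[int(a)].add(int(b))
                adj[int(b)].add(int(a))
    return adj


def euclidean_neighbors(
    s: ProteinStructure, r: int, radius: float = DEFAULT_RADIUS
) -> NeighborSet:
    """Residues whose minimum heavy-atom distance to residue ``r`` is ≤ ``radius`` (5 Å default)."""
    if not (0 <= r < len(s)):
        raise IndexError(f"residue index {r} out of range for {len(s)} residues")
    adj = euclidean_adjacency(s, radius=radius)
    return NeighborSet(center=r, neighbors=frozenset(adj[r]), kind="euclidean")


def _jittered(coords: np.ndarray, structure_id: str, sigma: float = 1e-6) -> np.ndarray:
    seed = zlib.crc32(structure_id.encode()) % (2**31)
    rng = np.random.default_rng(seed)
    return coords + rng.normal(scale=sigma, size=coords.shape)


def voronoi_adjacency(s: ProteinStructure, jitter: bool = False) -> dict:
    """Residue adjacency from the Delaunay tessellation of all heavy atoms.

    Two residues are neighbors iff some Delaunay edge joins an atom of one to
    an atom of the other (atom-level Voronoi facet sharing).  Degenerate
    coordinates raise unless ``jitter=True``, which applies a deterministic
    1e-6 Å perturbation seeded from the structure id.
    """
    coords, owner = _atom_table(s)
    if len(coords) < 4:
        raise ValueError("need at least 4 heavy atoms for a 3-D tessellation")
    if jitter:
        coords = _jittered(coords, s.structure_id)
    try:
        tri = Delaunay(coords)
    except QhullError as e:
        raise ValueError(
            "degenerate atom coordinates (coplanar or co-spherical); "
            "retry with jitter=True for a deterministic 1e-6 Å perturbation"
        ) from e
    adj = {r.seq_index: set() for r in s.residues}
    for simplex in tri.simplices:
        res = owner[simplex]
        for i in range(4):
            for j in range(i + 1, 4):
                a, b = int(res[i]), int(res[j])
                if a != b:
                    adj[a].add(b)
                    adj[b].add(a)
    return adj


def voronoi_neighbors(s: ProteinStructure, r: int, jitter: bool = False) -> NeighborSet:
    """Residues sharing at least one atom-level Voronoi facet with residue ``r``."""
    if not (0 <= r < len(s)):
        raise IndexError(f"residue index {r} out of range for {len(s)} residues")
    adj = voronoi_adjacency(s, jitter=jitter)
    return NeighborSet(center=r, neighbors=frozenset(adj[r]), kind="voronoi")


# ---------------------------------------------------------------------------
# feature aggregation


def _neighbor_sum(bft: BaseFeatureTable, neighbors, i: int) -> float:
    if not neighbors:
        return 0.0
    return float(bft.values[sorted(neighbors), i].sum())


def euclidean_feature(
    s: ProteinStructure,
    bft: BaseFeatureTable,
    r: int,
    i: int,
    radius: float = DEFAULT_RADIUS,
    semantics: str = "neighbor_sum",
) -> float:
    """Euclidean neighborhood score of base feature ``i`` at residue ``r``.

    Default semantics sum the neighbors' scores; ``semantics="center_times_m"``
    instead multiplies the center residue's own score by the neighbor count
    (the alternative literal reading of the defining sum).
    """
    ns = euclidean_neighbors(s, r, radius=radius)
    if semantics == "neighbor_sum":
        return _neighbor_sum(bft, ns.neighbors, i)
    if semantics == "center_times_m":
        return float(len(ns.neighbors) * bft.values[r, i])
    raise ValueError(f"unknown euclidean semantics {semantics!r}")


def voronoi_feature(
    s: ProteinStructure, bft: BaseFeatureTable, r: int, i: int, jitter: bool = False
) -> float:
    """Voronoi neighborhood score: sum of base feature ``i`` over the Voronoi
    neighbors of residue ``r``."""
    ns = voronoi_neighbors(s, r, jitter=jitter)
    return _neighbor_sum(bft, ns.neighbors, i)


def sequence_window_encode(
    bft: BaseFeatureTable, r: int, window: int = DEFAULT_WINDOW
) -> np.ndarray:
    """Concatenate the base feature rows at offsets −(w−1)/2 … +(w−1)/2
    around residue ``r`` (offset-major order); positions beyond either chain
    end contribute zeros."""
    if window % 2 != 1 or window < 1:
        raise ValueError("window must be a positive odd integer")
    n = bft.n_residues
    if not (0 <= r < n):
        raise IndexError(f"residue index {r} out of range for {n} residues")
    half = (window - 1) // 2
    blocks = []
    for offset in range(-half, half + 1):
        pos = r + offset
        if 0 <= pos < n:
            blocks.append(bft.values[pos])
        else:
            blocks.append(np.zeros(bft.n_features))
    return np.concatenate(blocks)


def window_feature_names(base_names, window: int = DEFAULT_WINDOW) -> list:
    half = (window - 1) // 2
    return [f"seq[{o:+d}]:{b}" for o in range(-half, half + 1) for b in base_names]


class NeighborhoodEncoder:
    """Encode variants on one structure, computing both neighbor relations once.

    Parameters
    ----------
    s : ProteinStructure
    radius : float
        Euclidean neighborhood cutoff in Å (default 5.0).
    window : int
        Odd sliding-window length along the sequence (default 11).
    euclidean_semantics : {"neighbor_sum", "center_times_m"}
    jitter : bool
        Deterministic degeneracy fallback for the Delaunay tessellation.
    """

    def __init__(
        self,
        s: ProteinStructure,
        radius: float = DEFAULT_RADIUS,
        window: int = DEFAULT_WINDOW,
        euclidean_semantics: str = "neighbor_sum",
        jitter: bool = False,
    ):
        if window % 2 != 1 or window < 1:
            raise ValueError("window must be a positive odd integer")
        if euclidean_semantics not in ("neighbor_sum", "center_times_m"):
            raise ValueError(f"unknown euclidean semantics {euclidean_semantics!r}")
        self.structure = s
        self.radius = radius
        self.window = window
        self.euclidean_semantics = euclidean_semantics
        self._euc = euclidean_adjacency(s, radius=radius)
        self._vor = voronoi_adjacency(s, jitter=jitter)

    def feature_names(self, base_names) -> list:
        return (
            window_feature_names(base_names, self.window)
            + [f"euc:{b}" for b in base_names]
            + [f"vor:{b}" for b in base_names]
        )

    def provenance(self, n_base: int) -> list:
        half = (self.window - 1) // 2
        prov = [f"seq[{o:+d}]" for o in range(-half, half + 1) for _ in range(n_base)]
        prov += ["euclidean"] * n_base + ["voronoi"] * n_base
        return prov

    def _aggregate(self, bft: BaseFeatureTable, r: int, adj: dict) -> np.ndarray:
        nbrs = sorted(adj[r])
        if not nbrs:
            return np.zeros(bft.n_features)
        return bft.values[nbrs].sum(axis=0)

    def encode(self, bft: BaseFeatureTable, r: int) -> EncodedVariant:
        if bft.n_residues != len(self.structure):
            raise ValueError(
                f"base table has {bft.n_residues} rows for a "
                f"{len(self.structure)}-residue structure"
            )
        seq = sequence_window_encode(bft, r, window=self.window)
        if self.euclidean_semantics == "neighbor_sum":
            euc = self._aggregate(bft, r, self._euc)
        else:
            euc = len(self._euc[r]) * bft.values[r]
        vor = self._aggregate(bft, r, self._vor)
        vector = np.concatenate([seq, euc, vor])
        return EncodedVariant(
            names=self.feature_names(bft.feature_names),
            vector=vector,
            provenance=self.provenance(bft.n_features),
        )


def encode_variant(
    s: ProteinStructure,
    bft: BaseFeatureTable,
    r: int,
    radius: float = DEFAULT_RADIUS,
    window: int = DEFAULT_WINDOW,
    euclidean_semantics: str = "neighbor_sum",
    jitter: bool = False,
) -> EncodedVariant:
    """Full encoding of the variant at residue ``r``:
    ``[sequence window | Euclidean | Voronoi]``, length ``window·B + 2B``
    (1521 for B = 117, window 11)."""
    enc = NeighborhoodEncoder(
        s, radius=radius, window=window, euclidean_semantics=euclidean_semantics, jitter=jitter
    )
    return enc.encode(bft, r)
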