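"""Four-body statistical pseudo-potential from Delaunay tessellation.

Each residue is reduced to its heavy-atom centroid; the Delaunay
tessellation of those centers partitions the protein into tetrahedra whose
vertices are amino acid quadruplets.  For a quadruplet composition (an
unordered 4-multiset of residue types) the potential is the log-ratio

    Q = ln (f + ε) / (p + ε)

of its observed frequency f among tetrahedra in a reference corpus to its
expected frequency p under independent sampling of residue types,

    p = (4! / Π_t c_t!) · Π a_t^{c_t},

where a_t are the corpus residue-type fractions and c_t the multiplicities
in the composition.  A pseudocount ε (default 1/(2·total tetrahedra))
smooths unseen compositions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from predsav.structure import AMINO_ACIDS, ProteinStructure
from predsav.neighborhood import _jittered


@dataclass(frozen=True)
class Tetrahedron:
    """One Delaunay simplex over residue centers."""

    vertices: tuple  # 4 distinct seq_index
    composition: str  # sorted 4-letter amino acid string

    def __post_init__(self):
        if len(set(self.vertices)) != 4:
            raise ValueError("tetrahedron needs 4 distinct vertices")
        if "".join(sorted(self.composition)) != self.composition or len(self.composition) != 4:
            raise ValueError("composition must be a sorted 4-letter string")


@dataclass
class QuadrupletStats:
    """Observed quadruplet frequencies and residue-type fractions of a corpus."""

    observed: dict  # composition -> fraction of tetrahedra
    residue_freqs: dict  # one-letter AA -> fraction
    total_tetrahedra: int

    def __post_init__(self):
        if self.total_tetrahedra < 1:
            raise ValueError("corpus contains no tetrahedra")
        if abs(sum(self.observed.values()) - 1.0) > 1e-12:
            raise ValueError("observed frequencies must sum to 1")
        if abs(sum(self.residue_freqs.values()) - 1.0) > 1e-12:
            raise ValueError("residue frequencies must sum to 1")


def composition_of(s: ProteinStructure, vertices) -> str:
    return "".join(sorted(s.residues[v].aa for v in vertices))


def residue_delaunay(s: ProteinStructure, jitter: bool = False) -> list:
    """Delaunay tetrahedra over the residue centers of one structure.

    Degenerate center sets raise unless ``jitter=True`` (deterministic
    1e-6 Å perturbation seeded from the structure id).
    """
    if len(s) < 4:
        raise ValueError("need at least 4 residues for a tessellation")
    centers = s.centers()
    if jitter:
        centers = _jittered(centers, s.structure_id)
    try:
        tri = Delaunay(centers)
    except QhullError as e:
        raise ValueError(
            "degenerate residue centers (coplanar or co-spherical); "
            "retry with jitter=True for a deterministic 1e-6 Å perturbation"
        ) from e
    tets = []
    for simplex in tri.simplices:
        verts = tuple(sorted(int(v) for v in simplex))
        tets.append(Tetrahedron(vertices=verts, composition=composition_of(s, verts)))
    return tets


def count_quadruplet_stats(structures, jitter: bool = False) -> QuadrupletStats:
    """Pool tetrahedron-composition counts and residue-type fractions over a
    corpus of structures."""
    counts: Counter = Counter()
    aa_counts: Counter = Counter()
    for s in structures:
        for tet in residue_delaunay(s, jitter=jitter):
            counts[tet.composition] += 1
        aa_counts.update(r.aa for r in s.residues)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no tetrahedra found in the corpus")
    n_res = sum(aa_counts.values())
    return QuadrupletStats(
        observed={c: k / total for c, k in counts.items()},
        residue_freqs={aa: k / n_res for aa, k in aa_counts.items()},
        total_tetrahedra=total,
    )


def expected_frequency(composition: str, residue_freqs: dict) -> float:
    """Multinomial expectation of a quadruplet composition under independent
    residue-type sampling: (4!/Π c_t!)·Π a_t^{c_t}."""
    comp = "".join(sorted(composition))
    if len(comp) != 4:
        raise ValueError("composition must contain exactly 4 residues")
    mult = Counter(comp)
    p = math.factorial(4)
    for aa, c in mult.items():
        if aa not in residue_freqs:
            raise KeyError(f"residue type {aa!r} absent from residue_freqs")
        p *= residue_freqs[aa] ** c / math.factorial(c)
    return float(p)


def four_body_score(
    composition: str, stats: QuadrupletStats, pseudocount: float | None = None
) -> float:
    """Log-ratio potential Q = ln (f+ε)/(p+ε) of one composition.

    ``pseudocount=None`` uses the default ε = 1/(2·total tetrahedra);
    pass 0 for the raw log-ratio (which errors on p = 0).
    """
    eps = 1.0 / (2 * stats.total_tetrahedra) if pseudocount is None else pseudocount
    if eps < 0:
        raise ValueError("pseudocount must be non-negative")
    comp = "".join(sorted(composition))
    f = stats.observed.get(comp, 0.0)
    p = expected_frequency(comp, stats.residue_freqs)
    if p + eps == 0:
        raise ValueError(f"expected frequency of {comp} is 0 and pseudocount is 0")
    return float(np.log((f + eps) / (p + eps)))


def all_compositions(alphabet: str = AMINO_ACIDS):
    """All unordered 4-multisets over the alphabet (8855 for 20 amino acids)."""
    return ["".join(c) for c in combinations_with_replacement(sorted(alphabet), 4)]


def potential_table(stats: QuadrupletStats, pseudocount: float | None = None) -> pd.DataFrame:
    """Composition, observed f, expected p and Q for every observed composition."""
    eps = 1.0 / (2 * stats.total_tetrahedra) if pseudocount is None else pseudocount
    rows = []
    for comp in sorted(stats.observed):
        f = stats.observed[comp]
        p = expected_frequency(comp, stats.residue_freqs)
        rows.append(dict(composition=comp, f=f, p=p, Q=float(np.log((f + eps) / (p + eps)))))
    df = pd.DataFrame(rows)
    df.attrs["pseudocount"] = eps
    return df


def residue_mean_q(
    s: ProteinStructure, stats: QuadrupletStats, pseudocount: float | None = None,
    jitter: bool = False,
) -> np.ndarray:
    """Per-residue mean Q over the tetrahedra incident to each residue
    (0 for residues in no tetrahedron); usable as a base-feature column."""
    sums = np.zeros(len(s))
    counts = np.zeros(len(s))
    for tet in residue_delaunay(s, jitter=jitter):
        q = four_body_score(tet.composition, stats, pseudocount=pseudocount)
        for v in tet.vertices:
            sums[v] += q
            counts[v] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return out
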