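"""Residue-contact network and its eight per-residue descriptors.

Residues are nodes; an edge joins two residues whose heavy-atom centroids
lie within 6.5 Å.  For each residue the module reports betweenness (raw
shortest-path pair counts), closeness ((n_c−1)/Σd within the residue's
connected component), coreness (k-core number), degree, clustering
coefficient, eigenvector centrality (component-wise principal eigenvector,
L2-normalized, positive), eccentricity (within component) and the average
nearest-neighbor degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from predsav.structure import ProteinStructure

DEFAULT_CUTOFF = 6.5

METRIC_NAMES = [
    "betweenness",
    "closeness",
    "coreness",
    "degree",
    "clustering_coefficient",
    "eigenvector_centrality",
    "eccentricity",
    "avg_nearest_neighbor_degree",
]


@dataclass(frozen=True)
class NetworkFeatureRow:
    betweenness: float
    closeness: float
    coreness: int
    degree: int
    clustering_coefficient: float
    eigenvector_centrality: float
    eccentricity: int
    avg_nearest_neighbor_degree: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def build_contact_graph(
    s: ProteinStructure, cutoff: float = DEFAULT_CUTOFF, center_mode: str = "centroid"
) -> nx.Graph:
    """Simple undirected graph on seq_index with an edge wherever the
    residue-center distance is ≤ ``cutoff`` Å."""
    if len(s) < 2:
        raise ValueError("need at least 2 residues to build a contact graph")
    if center_mode == "centroid":
        centers = s.centers()
    else:
        from predsav.structure import residue_center

        centers = np.array([residue_center(r, mode=center_mode) for r in s.residues])
    d = squareform(pdist(centers))
    g = nx.Graph(cutoff=cutoff)
    g.add_nodes_from(range(len(s)))
    ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def _componentwise_eigenvector(g: nx.Graph) -> dict:
    """Principal adjacency eigenvector per connected component, entries made
    positive and L2-normalized within the component.  Singleton components
    get the trivial unit entry 1.0."""
    cent = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            cent[nodes[0]] = 1.0
            continue
        a = nx.to_numpy_array(g, nodelist=nodes)
        w, v = np.linalg.eigh(a)
        vec = v[:, np.argmax(w)]
        # Perron vector of a connected non-negative matrix has one sign
        if vec.sum() < 0:
            vec = -vec
        vec = np.abs(vec)
        vec = vec / np.linalg.norm(vec)
        for node, val in zip(nodes, vec):
            cent[node] = float(val)
    return cent


def network_features(g: nx.Graph, r: int) -> NetworkFeatureRow:
    """The eight contact-network descriptors of node ``r``."""
    if r not in g:
        raise KeyError(f"residue {r} is not a node of the contact graph")
    return network_feature_rows(g)[r]


def network_feature_rows(g: nx.Graph) -> dict:
    """All eight descriptors for every node (computed in one pass)."""
    betweenness = nx.betweenness_centrality(g, normalized=False)
    clustering = nx.clustering(g)
    coreness = nx.core_number(g)
    eig = _componentwise_eigenvector(g)
    annd = nx.average_neighbor_degree(g)

    closeness, eccentricity = {}, {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        n_c = len(comp)
        for node in comp:
            lengths = nx.single_source_shortest_path_length(sub, node)
            total = sum(lengths.values())
            closeness[node] = (n_c - 1) / total if total > 0 else 0.0
            eccentricity[node] = max(lengths.values())

    rows = {}
    for node in g.nodes:
        deg = g.degree(node)
        rows[node] = NetworkFeatureRow(
            betweenness=float(betweenness[node]),
            closeness=float(closeness[node]),
            coreness=int(coreness[node]),
            degree=int(deg),
            clustering_coefficient=float(clustering[node]),
            eigenvector_centrality=float(eig[node]),
            eccentricity=int(eccentricity[node]),
            avg_nearest_neighbor_degree=float(annd[node]) if deg > 0 else 0.0,
        )
    return rows


def network_feature_table(
    s: ProteinStructure, cutoff: float = DEFAULT_CUTOFF, center_mode: str = "centroid"
):
    """Per-residue table of the eight metrics, usable as extra base-feature
    columns."""
    import pandas as pd

    g = build_contact_graph(s, cutoff=cutoff, center_mode=center_mode)
    rows = network_feature_rows(g)
    df = pd.DataFrame([rows[i].as_dict() for i in range(len(s))])
    df.insert(0, "aa", [r.aa for r in s.residues])
    df.insert(0, "auth_number", [r.auth_number for r in s.residues])
    df.insert(0, "chain", [r.chain_id for r in s.residues])
    return df
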