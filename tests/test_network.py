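"""Contact graph construction and the eight per-residue network metrics."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from predsav.network import build_contact_graph, network_feature_rows, network_features
from predsav.structure import residue_center
from conftest import point_structure


# ---------------------------------------------------------------------------
# independent brute-force implementations (BFS, triangle enumeration,
# power iteration)


def bfs_lengths(adj, src):
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def bfs_path_counts(adj, src):
    """Shortest-path distances and counts from src."""
    dist = bfs_lengths(adj, src)
    order = sorted(dist, key=dist.get)
    sigma = {v: 0 for v in dist}
    sigma[src] = 1
    for v in order[1:]:
        sigma[v] = sum(sigma[u] for u in adj[v] if dist.get(u) == dist[v] - 1)
    return dist, sigma


def brute_metrics(adj):
    """All eight metrics from scratch."""
    nodes = sorted(adj)
    deg = {v: len(adj[v]) for v in nodes}

    clustering = {}
    for v in nodes:
        k = deg[v]
        if k < 2:
            clustering[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(sorted(adj[v]), 2) if b in adj[a])
        clustering[v] = links / (k * (k - 1) / 2)

    betweenness = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist, sigma = bfs_path_counts(adj, s)
        if t not in dist:
            continue
        for v in nodes:
            if v in (s, t) or v not in dist:
                continue
            if dist[v] + bfs_lengths(adj, v).get(t, np.inf) == dist[t]:
                _, sigma_v = bfs_path_counts(adj, v)
                betweenness[v] += sigma[v] * sigma_v.get(t, 0) / sigma[t]

    closeness, eccentricity = {}, {}
    for v in nodes:
        dist = bfs_lengths(adj, v)
        total = sum(dist.values())
        closeness[v] = (len(dist) - 1) / total if total > 0 else 0.0
        eccentricity[v] = max(dist.values())

    # k-core by repeated pruning
    coreness = {}
    remaining = {v: set(adj[v]) for v in nodes}
    k = 0
    while remaining:
        while True:
            prune = [v for v, nb in remaining.items() if len(nb) <= k]
            if not prune:
                break
            for v in prune:
                coreness[v] = k
                for u in remaining[v]:
                    remaining[u].discard(v)
                del remaining[v]
        k += 1

    # component-wise principal eigenvector via power iteration
    eig = {}
    seen = set()
    for v in nodes:
        if v in seen:
            continue
        comp = sorted(bfs_lengths(adj, v))
        seen.update(comp)
        if len(comp) == 1:
            eig[comp[0]] = 1.0
            continue
        idx = {u: i for i, u in enumerate(comp)}
        a = np.zeros((len(comp), len(comp)))
        for u in comp:
            for w in adj[u]:
                a[idx[u], idx[w]] = 1.0
        x = np.ones(len(comp)) / np.sqrt(len(comp))
        for _ in range(100000):
            # shift to guarantee convergence for bipartite components
            y = a @ x + x
            y = y / np.linalg.norm(y)
            if np.linalg.norm(y - x) < 1e-13:
                break
            x = y
        x = np.abs(x / np.linalg.norm(x))
        for u in comp:
            eig[u] = x[idx[u]]

    annd = {
        v: (sum(deg[u] for u in adj[v]) / deg[v] if deg[v] else 0.0) for v in nodes
    }
    return dict(
        betweenness=betweenness, closeness=closeness, coreness=coreness,
        degree=deg, clustering_coefficient=clustering,
        eigenvector_centrality=eig, eccentricity=eccentricity,
        avg_nearest_neighbor_degree=annd,
    )


def graph_to_adj(g):
    return {v: set(g.neighbors(v)) for v in g.nodes}


class TestBuildContactGraph:
    def test_distant_residues_unconnected(self):
        s = point_structure([[0, 0, 0], [10, 0, 0]])
        assert build_contact_graph(s).number_of_edges() == 0

    def test_collinear_path_graph(self):
        s = point_structure([[0, 0, 0], [6, 0, 0], [12, 0, 0]])
        g = build_contact_graph(s)  # 6 <= 6.5 < 12
        assert sorted(g.edges) == [(0, 1), (1, 2)]

    def test_edges_match_brute_force_distances(self, helix30):
        g = build_contact_graph(helix30)
        centers = [residue_center(r) for r in helix30.residues]
        for i in range(len(helix30)):
            for j in range(i + 1, len(helix30)):
                expected = np.linalg.norm(centers[i] - centers[j]) <= 6.5
                assert g.has_edge(i, j) == expected

    def test_cutoff_monotone(self, helix30):
        e_small = set(build_contact_graph(helix30, cutoff=5.0).edges)
        e_large = set(build_contact_graph(helix30, cutoff=8.0).edges)
        assert e_small <= e_large

    def test_single_residue_rejected(self):
        s = point_structure([[0, 0, 0]])
        with pytest.raises(ValueError):
            build_contact_graph(s)


class TestNetworkFeatures:
    def test_triangle_graph_values(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2)])
        row = network_features(g, 0)
        assert row.degree == 2
        assert row.clustering_coefficient == 1.0
        assert row.eccentricity == 1
        assert row.coreness == 2
        assert row.betweenness == 0.0
        assert row.eigenvector_centrality == pytest.approx(1 / np.sqrt(3))

    def test_path_graph_middle_node(self):
        g = nx.Graph([(0, 1), (1, 2)])
        row = network_features(g, 1)
        assert row.degree == 2
        assert row.clustering_coefficient == 0.0
        assert row.betweenness == 1.0  # the single dependent pair (0,2)
        assert row.eccentricity == 1
        assert row.avg_nearest_neighbor_degree == 1.0

    def test_missing_node_raises(self):
        g = nx.Graph([(0, 1)])
        with pytest.raises(KeyError):
            network_features(g, 5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        g = nx.gnp_random_graph(18, rng.uniform(0.08, 0.4), seed=seed)
        rows = network_feature_rows(g)
        expected = brute_metrics(graph_to_adj(g))
        for v in g.nodes:
            got = rows[v].as_dict()
            for metric, table in expected.items():
                assert got[metric] == pytest.approx(table[v], abs=1e-8), (
                    f"{metric} differs at node {v} (seed {seed})"
                )

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(12, 0.3, seed=4)
        perm = {v: (v * 5 + 3) % 12 for v in g.nodes}
        h = nx.relabel_nodes(g, perm)
        rows_g = network_feature_rows(g)
        rows_h = network_feature_rows(h)
        for v in g.nodes:
            assert rows_g[v].as_dict() == pytest.approx(rows_h[perm[v]].as_dict())

    def test_degree_sum_and_triangle_free_clustering(self):
        g = nx.cycle_graph(8)  # triangle-free
        rows = network_feature_rows(g)
        assert sum(r.degree for r in rows.values()) == 2 * g.number_of_edges()
        assert all(r.clustering_coefficient == 0 for r in rows.values())

    def test_isolated_node_conventions(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1, 2])
        g.add_edge(1, 2)
        row = network_features(g, 0)
        assert row.degree == 0
        assert row.closeness == 0.0
        assert row.avg_nearest_neighbor_degree == 0.0
        assert row.eigenvector_centrality == 1.0  # trivial singleton component
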