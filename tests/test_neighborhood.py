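"""Euclidean/Voronoi neighborhoods, window encoding and the full variant vector."""

import numpy as np
import pytest

from predsav.neighborhood import (
    BaseFeatureTable,
    NeighborhoodEncoder,
    encode_variant,
    euclidean_feature,
    euclidean_neighbors,
    sequence_window_encode,
    voronoi_adjacency,
    voronoi_feature,
    voronoi_neighbors,
    window_feature_names,
)
from predsav.structure import min_heavy_atom_distance
from predsav.fixtures import generate_base_features
from conftest import point_structure


def brute_euclidean_adjacency(s, radius):
    n = len(s)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if min_heavy_atom_distance(s.residues[i], s.residues[j]) <= radius:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def circumsphere(p):
    """Center/radius of the sphere through 4 points (rows of p)."""
    a = 2 * (p[1:] - p[0])
    b = (p[1:] ** 2).sum(axis=1) - (p[0] ** 2).sum()
    center = np.linalg.solve(a, b)
    return center, np.linalg.norm(p[0] - center)


def brute_delaunay_edges(points):
    """Atom pairs joined by a Delaunay edge, from the empty-circumsphere
    property checked over every 4-point subset."""
    from itertools import combinations

    points = np.asarray(points, dtype=float)
    edges = set()
    for quad in combinations(range(len(points)), 4):
        p = points[list(quad)]
        try:
            center, radius = circumsphere(p)
        except np.linalg.LinAlgError:
            continue
        others = [k for k in range(len(points)) if k not in quad]
        if all(np.linalg.norm(points[k] - center) > radius + 1e-9 for k in others):
            for u, v in combinations(quad, 2):
                edges.add((min(u, v), max(u, v)))
    return edges


class TestEuclideanNeighbors:
    def test_isolated_residue_has_no_neighbors(self):
        s = point_structure([[0, 0, 0], [1, 0, 0], [100, 0, 0], [1, 1, 0], [0, 1, 1]])
        assert euclidean_neighbors(s, 2).neighbors == frozenset()

    def test_collinear_single_atom_residues(self):
        s = point_structure([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        assert euclidean_neighbors(s, 1).neighbors == frozenset({0, 2})
        assert euclidean_neighbors(s, 0).neighbors == frozenset({1})
        assert euclidean_neighbors(s, 2).neighbors == frozenset({1})

    def test_matches_brute_force_on_structure(self, helix30):
        brute = brute_euclidean_adjacency(helix30, 5.0)
        for r in range(len(helix30)):
            assert euclidean_neighbors(helix30, r).neighbors == frozenset(brute[r])

    def test_symmetric_antireflexive_and_radius_monotone(self, helix30):
        small = {r: euclidean_neighbors(helix30, r, radius=4.0).neighbors
                 for r in range(len(helix30))}
        large = {r: euclidean_neighbors(helix30, r, radius=6.0).neighbors
                 for r in range(len(helix30))}
        for r in range(len(helix30)):
            assert r not in large[r]
            assert small[r] <= large[r]
            for n in large[r]:
                assert r in large[n]

    def test_invalid_index_raises(self, helix30):
        with pytest.raises(IndexError):
            euclidean_neighbors(helix30, len(helix30))


class TestVoronoiNeighbors:
    def test_tetrahedron_vertices_all_mutually_adjacent(self):
        s = point_structure(
            [[0, 0, 0], [1, 0, 0.02], [0.5, 0.9, 0.01], [0.5, 0.3, 0.8]]
        )
        for r in range(4):
            assert voronoi_neighbors(s, r).neighbors == frozenset(range(4)) - {r}

    def test_matches_empty_circumsphere_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.normal(size=(12, 3)) * 5
            s = point_structure(pts)
            expected = brute_delaunay_edges(pts)
            adj = voronoi_adjacency(s)
            got = {(min(a, b), max(a, b)) for a in adj for b in adj[a]}
            assert got == expected

    def test_symmetric_and_self_free_on_helix(self, helix30):
        adj = voronoi_adjacency(helix30)
        for r, nbrs in adj.items():
            assert r not in nbrs
            for n in nbrs:
                assert r in adj[n]

    def test_degenerate_coordinates_error_advises_jitter(self):
        xs, ys = np.meshgrid(np.arange(3.0), np.arange(3.0))
        planar = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(9)])
        s = point_structure(planar)
        with pytest.raises(ValueError, match="jitter"):
            voronoi_neighbors(s, 0)
        ns = voronoi_neighbors(s, 0, jitter=True)  # deterministic fallback
        assert ns.neighbors == voronoi_neighbors(s, 0, jitter=True).neighbors


class TestFeatureAggregation:
    def test_no_neighbors_sum_to_zero(self):
        s = point_structure([[0, 0, 0], [1, 0, 0], [100, 0, 0], [1, 1, 0], [0, 1, 1]])
        bft = BaseFeatureTable(["a"], np.arange(5.0)[:, None])
        assert euclidean_feature(s, bft, 2, 0) == 0.0

    def test_two_neighbor_scores_sum(self):
        s = point_structure([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        bft = BaseFeatureTable(["a"], np.array([[0.2], [0.7], [0.3]]))
        assert euclidean_feature(s, bft, 1, 0) == pytest.approx(0.5)

    def test_center_times_m_semantics(self):
        s = point_structure([[0, 0, 0], [4, 0, 0], [8, 0, 0]])
        bft = BaseFeatureTable(["a"], np.array([[0.2], [0.7], [0.3]]))
        got = euclidean_feature(s, bft, 1, 0, semantics="center_times_m")
        assert got == pytest.approx(2 * 0.7)

    def test_voronoi_sum_of_three_neighbors(self):
        s = point_structure(
            [[0, 0, 0], [1, 0, 0.02], [0.5, 0.9, 0.01], [0.5, 0.3, 0.8]]
        )
        bft = BaseFeatureTable(["a"], np.array([[9.0], [1.0], [2.0], [3.0]]))
        assert voronoi_feature(s, bft, 0, 0) == pytest.approx(6.0)

    def test_random_structure_matches_bruteforce_loops(self, helix30, helix30_features):
        brute = brute_euclidean_adjacency(helix30, 5.0)
        vor = voronoi_adjacency(helix30)
        for r in [0, 7, 15, 29]:
            for i in range(helix30_features.n_features):
                exp_e = sum(helix30_features.values[n, i] for n in brute[r])
                exp_v = sum(helix30_features.values[n, i] for n in vor[r])
                assert euclidean_feature(helix30, helix30_features, r, i) == pytest.approx(exp_e)
                assert voronoi_feature(helix30, helix30_features, r, i) == pytest.approx(exp_v)


class TestSequenceWindow:
    def test_single_residue_chain_pads_with_zeros(self):
        bft = BaseFeatureTable(["a", "b"], np.array([[1.0, 2.0]]))
        vec = sequence_window_encode(bft, 0, window=3)
        np.testing.assert_allclose(vec, [0, 0, 1, 2, 0, 0])

    def test_center_block_is_the_residue_row(self, helix30_features):
        r, w = 7, 11
        vec = sequence_window_encode(helix30_features, r, window=w)
        B = helix30_features.n_features
        center = vec[(w // 2) * B : (w // 2 + 1) * B]
        np.testing.assert_array_equal(center, helix30_features.values[r])

    @pytest.mark.parametrize("window", [3, 5, 11])
    def test_matches_index_arithmetic_oracle(self, window):
        rng = np.random.default_rng(23)
        bft = BaseFeatureTable([f"x{i}" for i in range(4)], rng.normal(size=(15, 4)))
        half = (window - 1) // 2
        for r in range(15):
            vec = sequence_window_encode(bft, r, window=window)
            expected = []
            for off in range(-half, half + 1):  # explicit loop oracle
                for i in range(4):
                    p = r + off
                    expected.append(bft.values[p, i] if 0 <= p < 15 else 0.0)
            np.testing.assert_allclose(vec, expected)

    def test_even_window_rejected(self, helix30_features):
        with pytest.raises(ValueError):
            sequence_window_encode(helix30_features, 0, window=4)


class TestEncodeVariant:
    def test_117_base_features_give_1521(self, helix30):
        bft = generate_base_features(helix30, n_features=117, seed=0)
        ev = encode_variant(helix30, bft, 10)
        assert len(ev.vector) == 1521
        assert sum(p.startswith("seq") for p in ev.provenance) == 1287
        assert sum(p == "euclidean" for p in ev.provenance) == 117
        assert sum(p == "voronoi" for p in ev.provenance) == 117
        assert len(set(ev.names)) == 1521

    def test_small_dimensions(self, helix30):
        bft = generate_base_features(helix30, n_features=2, seed=0)
        ev = encode_variant(helix30, bft, 10, window=3)
        assert len(ev.vector) == 3 * 2 + 2 + 2

    def test_blockwise_equality_with_components(self, helix30, helix30_features):
        r = 12
        ev = encode_variant(helix30, helix30_features, r)
        B = helix30_features.n_features
        np.testing.assert_allclose(
            ev.vector[: 11 * B], sequence_window_encode(helix30_features, r, 11)
        )
        for i in range(B):
            assert ev.vector[11 * B + i] == pytest.approx(
                euclidean_feature(helix30, helix30_features, r, i)
            )
            assert ev.vector[12 * B + i] == pytest.approx(
                voronoi_feature(helix30, helix30_features, r, i)
            )

    def test_linear_in_base_table_and_zero_maps_to_zero(self, helix30):
        rng = np.random.default_rng(2)
        names = ["a", "b", "c"]
        P = rng.normal(size=(30, 3))
        Q = rng.normal(size=(30, 3))
        alpha, beta = 0.7, -1.3
        enc = NeighborhoodEncoder(helix30)
        vp = enc.encode(BaseFeatureTable(names, P), 9).vector
        vq = enc.encode(BaseFeatureTable(names, Q), 9).vector
        vmix = enc.encode(BaseFeatureTable(names, alpha * P + beta * Q), 9).vector
        np.testing.assert_allclose(vmix, alpha * vp + beta * vq, atol=1e-9)
        vzero = enc.encode(BaseFeatureTable(names, np.zeros((30, 3))), 9).vector
        np.testing.assert_array_equal(vzero, 0)

    def test_rigid_motion_invariance(self, helix30, helix30_features):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [31, -57, 113], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        import copy

        moved = copy.deepcopy(helix30)
        for res in moved.residues:
            for a in res.atoms:
                object.__setattr__(a, "coords", rot @ a.coords + shift)
        for r in [0, 11, 29]:
            v1 = encode_variant(helix30, helix30_features, r).vector
            v2 = encode_variant(moved, helix30_features, r).vector
            np.testing.assert_allclose(v1, v2, atol=1e-8)

    def test_feature_names_follow_convention(self, helix30_features):
        names = window_feature_names(["a", "b"], window=3)
        assert names == ["seq[-1]:a", "seq[-1]:b", "seq[+0]:a", "seq[+0]:b",
                         "seq[+1]:a", "seq[+1]:b"]
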