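import itertools

import numpy as np
import pytest
from scipy.spatial import Voronoi

from gridtopo import (
    Grid,
    build_delaunay,
    build_knn,
    make_grid,
    nearest_grid_point,
    validate_graph,
)


def brute_force_delaunay_edges_2d(pts):
    """Edges of all triangles passing the empty-circumcircle test."""
    n = len(pts)
    edges = set()
    for i, j, k in itertools.combinations(range(n), 3):
        a, b, c = pts[i], pts[j], pts[k]
        area2 = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(area2) < 1e-12:
            continue
        center, r = _circumcircle(a, b, c)
        ok = True
        for m in range(n):
            if m in (i, j, k):
                continue
            if np.linalg.norm(pts[m] - center) < r * (1 - 1e-9):
                ok = False
                break
        if ok:
            edges |= {(min(i, j), max(i, j)), (min(j, k), max(j, k)), (min(i, k), max(i, k))}
    return edges


def _circumcircle(a, b, c):
    A = 2 * np.array([b - a, c - a])
    rhs = np.array([b @ b - a @ a, c @ c - a @ a])
    center = np.linalg.solve(A, rhs)
    return center, np.linalg.norm(center - a)


def graph_edges(graph):
    return set(map(tuple, graph.edge_array().tolist()))


class TestDelaunay:
    def test_single_simplex_triangle(self):
        g = Grid(np.array([[0.0, 0], [1, 0], [0, 1]]))
        graph = build_delaunay(g)
        assert graph.n_edges == 3
        assert np.all(graph.degrees() == 2)
        assert graph.hull_mask.all()

    def test_four_points_match_circumcircle_oracle(self, tiny_grid_2d):
        graph = build_delaunay(tiny_grid_2d)
        expected = brute_force_delaunay_edges_2d(tiny_grid_2d.points)
        assert graph_edges(graph) == expected
        assert graph.n_edges == 5  # 4 boundary + 1 diagonal

    @pytest.mark.parametrize("n_pts", [30, 50])
    def test_empty_circumcircle_property_small_instances(self, n_pts):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=n_pts, seed=n_pts, weights=None)
        graph = build_delaunay(grid)
        assert graph_edges(graph) == brute_force_delaunay_edges_2d(grid.points)

    def test_bulk_nodes_all_move_preserving_on_random_grid(self):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=200, seed=7, weights=None)
        report = validate_graph(build_delaunay(grid))
        assert report.connected and report.undirected
        assert report.basis_preserving_fraction == 1.0
        assert report.move_preserving_fraction == 1.0

    def test_matches_voronoi_facet_adjacency(self):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=60, seed=2, weights=None)
        graph = build_delaunay(grid)
        vor = Voronoi(grid.points)
        vor_edges = {(min(a, b), max(a, b)) for a, b in vor.ridge_points}
        assert graph_edges(graph) == vor_edges

    def test_deterministic_for_fixed_jitter_seed(self):
        # cospherical/cocircular degeneracy: a perfect lattice
        grid = make_grid("uniform", spacing=1.0, shape=(5, 5))
        g1 = build_delaunay(grid, jitter_seed=4)
        g2 = build_delaunay(grid, jitter_seed=4)
        assert graph_edges(g1) == graph_edges(g2)
        assert g1.provenance["jitter_seed"] == 4

    def test_1d_chain(self):
        g = Grid(np.array([3.0, 0.0, 1.0, 2.0]))
        graph = build_delaunay(g)
        assert graph_edges(graph) == {(1, 2), (2, 3), (0, 3)}
        assert graph.hull_mask.sum() == 2


class TestKnn:
    def test_equal_spacing_k1_ties_resolve_to_lower_index(self):
        # hand enumeration: every interior node's nearest-neighbor tie goes to
        # its lower-indexed side, and the undirected union then restores every
        # consecutive pair
        g = Grid(np.arange(10.0))
        graph = build_knn(g, k=1)
        assert graph_edges(graph) == {(i, i + 1) for i in range(9)}

    def test_unequal_spacing_k1_fragments_into_pairs(self):
        # pairs of mutually-nearest points separated by wider gaps: the k=1
        # graph is disconnected (the failure mode triangulations avoid)
        g = Grid(np.array([0.0, 1.0, 3.0, 4.0, 6.0, 7.0]))
        graph = build_knn(g, k=1)
        assert graph_edges(graph) == {(0, 1), (2, 3), (4, 5)}
        assert not validate_graph(graph).connected

    def test_k_equals_n_minus_1_is_complete(self):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=8, seed=0, weights=None)
        graph = build_knn(grid, k=7)
        assert graph.n_edges == 8 * 7 // 2

    def test_k2_violates_move_preservation_somewhere(self):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=120, seed=1, weights=None)
        report = validate_graph(build_knn(grid, 2))
        assert report.move_preserving_fraction < 1.0

    @pytest.mark.parametrize("k", [0, -1, 400])
    def test_k_out_of_range(self, k, random_grid_2d):
        grid, _ = random_grid_2d
        with pytest.raises(ValueError, match="k must"):
            build_knn(grid, k)

    def test_undirected_by_construction(self):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=50, seed=9, weights=None)
        assert validate_graph(build_knn(grid, 2)).undirected


class TestValidateMovePreserving:
    def test_one_sided_neighborhood_fails(self):
        # bulk node 0 with neighbors only along +x, -x, +y: no move has a
        # positive projection onto -y
        pts = np.array([[0.0, 0], [1, 0], [-1, 0], [0, 1],
                        [3, -3], [-3, -3], [0, 3.2]])  # outer shell forms the hull
        g = Grid(pts)
        from gridtopo.graphs import _move_preserving

        vecs = pts[[1, 2, 3]] - pts[0]
        assert not _move_preserving(vecs, 2)
        vecs_ok = pts[[1, 2, 3]] - pts[0]
        vecs_ok = np.vstack([vecs_ok, [0, -1]])
        assert _move_preserving(vecs_ok, 2)


def test_nearest_grid_point_is_grid_nearest(random_grid_2d):
    grid, _ = random_grid_2d
    q = np.array([0.123, -0.456])
    assert nearest_grid_point(grid, q) == grid.nearest(q)
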