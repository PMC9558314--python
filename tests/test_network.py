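import itertools

import networkx as nx
import numpy as np
import pytest

from gridtopo import (
    Grid,
    assign_basins_on_graph,
    build_delaunay,
    cleave,
    gap_fill,
    local_maxima,
    make_field,
    make_grid,
    max_spanning_tree,
    prune_to_critical_tree,
)
from conftest import hexagon_fixture


def path_grid(values):
    """1D chain grid whose Delaunay graph is the path 0-1-2-..."""
    g = Grid(np.arange(float(len(values))))
    return g, build_delaunay(g), np.asarray(values, dtype=float)


def maximin_bruteforce(G, f, x, y):
    """Widest-path value between x, y by enumerating all simple paths."""
    best = -np.inf
    for path in nx.all_simple_paths(G, x, y):
        w = min((f[a] + f[b]) / 2 for a, b in zip(path[:-1], path[1:]))
        best = max(best, w)
    return best


class TestMaxSpanningTree:
    def test_path_graph_tree_is_the_path(self):
        _, graph, f = path_grid([3.0, 1.0, 2.0, 5.0])
        tree = max_spanning_tree(graph, f)
        assert {tuple(e) for e in tree.tolist()} == {(0, 1), (1, 2), (2, 3)}

    def test_triangle_drops_lowest_average_edge(self):
        g = Grid(np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.9]]))
        graph = build_delaunay(g)
        f = np.array([3.0, 2.0, 1.0])
        tree = {tuple(e) for e in max_spanning_tree(graph, f).tolist()}
        assert tree == {(0, 1), (0, 2)}  # weights 2.5 and 2.0 beat 1.5

    def test_disconnected_graph_reports_components(self):
        from gridtopo import build_knn

        g = Grid(np.array([0.0, 1.0, 3.0, 4.0, 6.0, 7.0]))
        graph = build_knn(g, 1)  # mutually-nearest pairs: 3 components
        with pytest.raises(ValueError, match="disconnected.*3 components"):
            max_spanning_tree(graph, np.arange(6.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_tree_paths_achieve_brute_force_maximin(self, seed):
        rng = np.random.default_rng(seed)
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=14, seed=seed, weights=None)
        graph = build_delaunay(grid)
        f = rng.normal(size=grid.n)
        G = graph.to_networkx()
        tree_edges = max_spanning_tree(graph, f)
        T = nx.Graph(list(map(tuple, tree_edges.tolist())))
        maxima = local_maxima(graph, f)
        for x, y in itertools.combinations(map(int, maxima), 2):
            p = nx.shortest_path(T, x, y)
            tree_min = min((f[a] + f[b]) / 2 for a, b in zip(p[:-1], p[1:]))
            assert tree_min == pytest.approx(maximin_bruteforce(G, f, x, y), rel=1e-12)


class TestPruning:
    def test_path_with_interior_minimum(self):
        _, graph, f = path_grid([3.0, 1.0, 2.0, 5.0])
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, [0, 3], n_nodes=4)
        assert net.edges == {(0, 1), (1, 2), (2, 3)}  # nothing to prune
        assert net.critical_points[(0, 3)] == (1, 1.0)

    def test_star_prunes_all_non_maximum_leaves(self):
        g = Grid(np.array([[0.0, 0.0], [1.0, 0.0], [-0.5, 0.9], [-0.5, -0.9]]))
        graph = build_delaunay(g)
        f = np.array([5.0, 1.0, 2.0, 3.0])
        tree = np.array([[0, 1], [0, 2], [0, 3]])
        net = prune_to_critical_tree(tree, f, [0], n_nodes=4)
        assert net.edges == set()
        assert net.nodes.tolist() == [0]

    def test_two_gaussian_critical_value_matches_saddle(self, two_gaussian_model):
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=3000, seed=18, weights=None)
        graph = build_delaunay(grid)
        f = two_gaussian_model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, basins.local_maxima, n_nodes=grid.n)
        assert len(net.critical_points) == 1
        (pair, (node, value)), = net.critical_points.items()
        # analytic saddle of exp(-|x-a|^2)+exp(-|x-b|^2) sits at the midpoint
        saddle = 2 * np.exp(-1.0)
        assert value == pytest.approx(saddle, rel=0.02)
        assert np.linalg.norm(grid.points[node]) < 0.2

    def test_contains_all_maxima_and_is_acyclic(self):
        _, graph, f, _ = hexagon_fixture(seed=5, n=1500)
        basins = assign_basins_on_graph(graph, f)
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, basins.local_maxima, n_nodes=graph.n)
        G = nx.Graph(list(net.edges))
        assert all(int(m) in G for m in net.maxima)
        assert nx.is_forest(G)


class TestGapFill:
    def test_hexagon_ring_restored(self):
        grid, graph, f, centers = hexagon_fixture(seed=3, n=4000)
        basins = assign_basins_on_graph(graph, f)
        assert len(basins.local_maxima) == 6
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, basins.local_maxima, n_nodes=grid.n)
        vertex_nodes = [int(grid.nearest(c)) for c in centers]
        ring_pairs = {
            tuple(sorted((basins.attractor[vertex_nodes[i]],
                          basins.attractor[vertex_nodes[(i + 1) % 6]])))
            for i in range(6)
        }
        linked_before = set(net.critical_points) & ring_pairs
        assert len(linked_before) == 5  # the tree is acyclic: one ring link missing
        filled = gap_fill(net, graph, f, basins)
        linked_after = set(filled.critical_points) & ring_pairs
        assert len(linked_after) == 6
        assert len(filled.filled_edges) > 0
        # exactly one new ring pair, via filled edges only
        assert len(linked_after - linked_before) == 1
        assert not filled.filled_edges & net.edges

    def test_gap_filling_never_removes_edges(self):
        grid, graph, f, _ = hexagon_fixture(seed=3, n=4000)
        basins = assign_basins_on_graph(graph, f)
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, basins.local_maxima, n_nodes=grid.n)
        filled = gap_fill(net, graph, f, basins)
        assert net.edges <= filled.edges

    def test_boundary_touching_path_rejected(self):
        # three gaussian maxima in a row: the outer pair's best connecting
        # path must cross the middle basin, so within their two-basin
        # subgraph it hugs the boundary and is rejected
        model = make_field(
            "gaussian_mixture", centers=[(-2.0, 0.0), (0.0, 0.3), (2.0, 0.0)],
            heights=(1.0, 0.9, 1.0), widths=1.0,
        )
        grid = make_grid("random", bounds=[(-4, 4), (-2.5, 2.5)], n=3000, seed=10, weights=None)
        graph = build_delaunay(grid)
        f = model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        assert len(basins.local_maxima) == 3
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, basins.local_maxima, n_nodes=grid.n)
        filled = gap_fill(net, graph, f, basins)
        ends = sorted(
            (int(m) for m in basins.local_maxima),
            key=lambda m: grid.points[m][0],
        )
        outer_pair = (min(ends[0], ends[2]), max(ends[0], ends[2]))
        assert outer_pair not in filled.critical_points
        assert len(filled.filled_edges) == 0


class TestCleave:
    def _chain_network(self):
        # equal maxima at 0/10/20/30, shallow dips (0.95) between the first
        # three, one deep valley (0.2) before the last, decaying tails to 0
        values = np.zeros(37)
        maxima = [3, 13, 23, 33]
        for m in maxima:
            values[m] = 1.0
        for lo, hi, dip in ((3, 13, 0.95), (13, 23, 0.95), (23, 33, 0.2)):
            mid = (lo + hi) // 2
            values[lo + 1 : hi] = dip
            values[mid] = dip
        # linear tails down to 0 at the chain ends
        values[:3] = [0.0, 0.3, 0.6]
        values[34:] = [0.6, 0.3, 0.0]
        g, graph, f = path_grid(values)
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, maxima, n_nodes=g.n)
        return net, f

    def test_uniform_path_values_nothing_cleaved(self):
        _, graph, f = path_grid([1.0, 1.0, 1.0, 1.0, 0.0])  # last node sets f_min
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, [0, 3], n_nodes=5)
        cleaved = cleave(net, f, t_flat=0.25)
        assert cleaved.edges == net.edges

    def test_deep_valley_link_removed_shallow_kept(self):
        net, f = self._chain_network()
        devs = {}
        for (x, y), path in net.paths.items():
            s = f[path] / max(f[x], f[y])
            devs[(x, y)] = 1 - s.min()
        assert sorted(round(d, 2) for d in devs.values()) == [0.05, 0.05, 0.8]
        cleaved = cleave(net, f, t_flat=0.25)
        assert len(cleaved.paths) == 2
        assert cleaved.n_components() == 2
        assert cleaved.edges <= net.edges  # cleaving never adds edges

    def test_auto_threshold_separates_bimodal_deviations(self):
        net, f = self._chain_network()
        cleaved = cleave(net, f, t_flat="auto")
        assert 0.05 < cleaved.provenance["t_flat"] < 0.8
        assert len(cleaved.paths) == 2

    def test_ring_current_stagnation_line_splits_from_ring(self):
        # critical network of -|J| for a model ring current: the axial
        # stagnation line and the transverse features separate on cleaving
        model = make_field("ring_current")
        grid = make_grid("uniform", spacing=0.25, shape=(17, 17, 17),
                         origin=(-2.0, -2.0, -2.0))
        graph = build_delaunay(grid)
        f = -model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        tree = max_spanning_tree(graph, f)
        net = prune_to_critical_tree(tree, f, basins.local_maxima, n_nodes=grid.n)
        cleaved = cleave(net, f, t_flat="auto")
        assert cleaved.n_components() >= 2


class TestMonotoneInvariance:
    def test_critical_node_stable_under_cubing_positive_field(self):
        # a unique, well-separated saddle: the critical node must be found at
        # the same grid node whether ranked by f or by f^3
        model = make_field("two_gaussian", a=(-1.0, 0.0), b=(1.0, 0.0))
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=3000, seed=18, weights=None)
        graph = build_delaunay(grid)
        f = model.value(grid.points) + 0.01
        nets = []
        for field in (f, f**3):
            basins = assign_basins_on_graph(graph, field)
            tree = max_spanning_tree(graph, field)
            nets.append(prune_to_critical_tree(tree, field, basins.local_maxima,
                                               n_nodes=grid.n))
        cps1 = {pair: node for pair, (node, _) in nets[0].critical_points.items()}
        cps3 = {pair: node for pair, (node, _) in nets[1].critical_points.items()}
        assert cps1 == cps3
        (v1,) = (v for _, v in nets[0].critical_points.values())
        (v3,) = (v for _, v in nets[1].critical_points.values())
        assert v3 == pytest.approx(v1**3, rel=1e-12)
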