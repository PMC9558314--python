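import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridtopo import (
    ScalarField,
    assign_basins_off_graph,
    assign_basins_on_graph,
    build_delaunay,
    build_knn,
    cluster_maxima_families,
    field_on_grid,
    integrate_basins,
    local_maxima,
    ls_gradient,
    make_field,
    make_grid,
)
from gridtopo.basins import _steepest_successor


def trace_ascent_no_shortcut(graph, f):
    """Oracle: follow the steepest-ascent successor chain from every node."""
    successor = _steepest_successor(graph, np.asarray(f, dtype=float))
    attractor = np.empty(graph.n, dtype=np.int64)
    for i in range(graph.n):
        x = i
        while successor[x] >= 0:
            x = successor[x]
        attractor[i] = x
    return attractor


class TestLocalMaxima:
    def test_single_gaussian_single_maximum_nearest_center(self):
        model = make_field("gaussian_mixture", centers=[(0.3, -0.2)])
        grid = make_grid("random", bounds=[(-2, 2), (-2, 2)], n=500, seed=21, weights=None)
        graph = build_delaunay(grid)
        maxima = local_maxima(graph, model.value(grid.points))
        assert len(maxima) == 1
        assert maxima[0] == grid.nearest(np.array([0.3, -0.2]))

    def test_knn_graph_introduces_fictitious_maxima(self):
        model = make_field("gaussian_mixture", centers=[(0.3, -0.2)])
        grid = make_grid("random", bounds=[(-2, 2), (-2, 2)], n=500, seed=21, weights=None)
        graph = build_knn(grid, 2)
        maxima = local_maxima(graph, model.value(grid.points))
        assert len(maxima) > 1

    def test_constant_field_has_no_maxima(self, random_grid_2d):
        _, graph = random_grid_2d
        assert len(local_maxima(graph, np.ones(graph.n))) == 0


class TestOnGraphAssignment:
    def test_two_equal_gaussians_partition_grid(self, two_gaussian_model):
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=800, seed=4, weights=None)
        graph = build_delaunay(grid)
        basins = assign_basins_on_graph(graph, two_gaussian_model.value(grid.points))
        assert len(basins.local_maxima) == 2
        # each basin contains the node nearest its gaussian center
        na = grid.nearest(np.array([-1.0, 0.0]))
        nb = grid.nearest(np.array([1.0, 0.0]))
        assert basins.attractor[na] != basins.attractor[nb]
        # partition: every node assigned to one of the maxima
        assert set(np.unique(basins.attractor)) == set(basins.local_maxima.tolist())

    def test_single_maximum_field_one_basin(self):
        model = make_field("gaussian_mixture", centers=[(0.0, 0.0)])
        grid = make_grid("random", bounds=[(-2, 2), (-2, 2)], n=300, seed=6, weights=None)
        graph = build_delaunay(grid)
        basins = assign_basins_on_graph(graph, model.value(grid.points))
        assert len(np.unique(basins.attractor)) == 1

    def test_constant_field_raises(self, random_grid_2d):
        _, graph = random_grid_2d
        with pytest.raises(ValueError, match="no graph local maxima"):
            assign_basins_on_graph(graph, np.zeros(graph.n))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_shortcut_free_retrace_oracle(self, seed):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=30, seed=seed, weights=None)
        graph = build_delaunay(grid)
        f = np.random.default_rng(seed).normal(size=30)
        basins = assign_basins_on_graph(graph, f)
        np.testing.assert_array_equal(basins.attractor, trace_ascent_no_shortcut(graph, f))

    @given(scale=st.floats(0.1, 50.0), shift=st.floats(-5.0, 5.0))
    @settings(max_examples=20, deadline=None)
    def test_invariant_under_affine_rescaling_of_field(self, scale, shift):
        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=60, seed=77, weights=None)
        graph = build_delaunay(grid)
        f = np.random.default_rng(77).normal(size=60)
        a = assign_basins_on_graph(graph, f)
        b = assign_basins_on_graph(graph, scale * f + shift)
        np.testing.assert_array_equal(a.attractor, b.attractor)


class TestOffGraphAssignment:
    def test_single_maximum_matches_on_graph(self):
        model = make_field("gaussian_mixture", centers=[(0.0, 0.0)])
        grid = make_grid("random", bounds=[(-2, 2), (-2, 2)], n=400, seed=13, weights=None)
        graph = build_delaunay(grid)
        f = model.value(grid.points)
        grads = ls_gradient(graph, f)
        on = assign_basins_on_graph(graph, f)
        off = assign_basins_off_graph(graph, f, grads)
        np.testing.assert_array_equal(on.attractor, off.attractor)
        assert off.method == "off_graph"

    def test_maximum_node_assigned_to_itself(self, two_gaussian_model):
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=400, seed=14, weights=None)
        graph = build_delaunay(grid)
        f = two_gaussian_model.value(grid.points)
        off = assign_basins_off_graph(graph, f, ls_gradient(graph, f))
        for m in off.local_maxima:
            assert off.attractor[m] == m

    def test_reduces_misassignment_on_tilted_field(self):
        # two equal maxima whose axis is tilted against a uniform grid: the
        # analytic separatrix is the perpendicular bisector of the centers
        a, b = np.array([-1.0, -0.37]), np.array([1.0, 0.37])
        model = make_field("gaussian_mixture", centers=[a, b])
        grid = make_grid("uniform", spacing=4.0 / 40, shape=(40, 30), origin=(-2.0, -1.5))
        graph = build_delaunay(grid)
        f = model.value(grid.points)
        on = assign_basins_on_graph(graph, f)
        off = assign_basins_off_graph(graph, f, ls_gradient(graph, f))
        side = (grid.points - (a + b) / 2) @ (b - a) > 0
        na, nb = grid.nearest(a), grid.nearest(b)
        err_on = np.mean(side != (on.attractor == on.attractor[nb]))
        err_off = np.mean(side != (off.attractor == off.attractor[nb]))
        assert err_off < err_on


class TestMaximaFamilies:
    def test_ring_maxima_merge_into_one_family(self):
        model = make_field("ring", radius=1.0, dim=2)
        grid = make_grid("random", bounds=[(-2, 2), (-2, 2)], n=2000, seed=7, weights=None)
        graph = build_delaunay(grid)
        f = model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        assert len(basins.local_maxima) > 1  # extended maximum: many graph maxima
        fams = cluster_maxima_families(graph, f, basins, t=0.25)
        assert fams.n_families == 1

    def test_separated_gaussians_stay_singleton_families(self, two_gaussian_model):
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=800, seed=4, weights=None)
        graph = build_delaunay(grid)
        f = two_gaussian_model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        fams = cluster_maxima_families(graph, f, basins, t=0.25)
        assert fams.n_families == 2
        assert all(len(members) == 1 for members in fams.families)
        # the inter-peak valley is beyond tolerance: fills are disjoint
        assert not set(fams.flood_fills[0]) & set(fams.flood_fills[1])

    def test_tolerance_one_merges_everything_on_connected_graph(self, two_gaussian_model):
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=400, seed=9, weights=None)
        graph = build_delaunay(grid)
        f = two_gaussian_model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        fams = cluster_maxima_families(graph, f, basins, t=1.0)
        assert fams.n_families == 1

    @pytest.mark.parametrize("t", [0.0, -0.5, 1.5])
    def test_tolerance_out_of_range(self, t, two_gaussian_model):
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=100, seed=9, weights=None)
        graph = build_delaunay(grid)
        f = two_gaussian_model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        with pytest.raises(ValueError, match="tolerance"):
            cluster_maxima_families(graph, f, basins, t=t)


class TestFamilySweepEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("t", [0.1, 0.25, 0.6])
    def test_sweep_matches_literal_flood_fill(self, seed, t):
        """The merge-tree sweep must reproduce the per-maximum flood fills.

        Random rough fields on small graphs: both the family partition and
        the per-family covered node sets must agree with the brute-force
        fill-every-maximum-and-intersect oracle.
        """
        from gridtopo.basins import flood_fill_families_reference

        grid = make_grid("random", bounds=[(0, 1), (0, 1)], n=80, seed=seed, weights=None)
        graph = build_delaunay(grid)
        f = np.random.default_rng(seed).normal(size=grid.n)
        basins = assign_basins_on_graph(graph, f)
        fams = cluster_maxima_families(graph, f, basins, t=t)
        groups, covers = flood_fill_families_reference(graph, f, basins.local_maxima, t)
        got = {tuple(sorted(map(int, members))) for members in fams.families}
        expected = {tuple(sorted(g)) for g in groups.values()}
        assert got == expected
        got_covers = {tuple(sorted(map(int, fill))) for fill in fams.flood_fills}
        exp_covers = {tuple(sorted(c)) for c in covers.values()}
        assert got_covers == exp_covers


class TestBasinIntegration:
    def _setup(self, n=900, seed=15):
        model = make_field("two_gaussian", a=(-1.0, 0.0), b=(1.0, 0.0))
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=n, seed=seed)
        graph = build_delaunay(grid)
        f = field_on_grid(model, grid)
        basins = assign_basins_on_graph(graph, f)
        fams = cluster_maxima_families(graph, f, basins, t=0.25)
        return grid, f, basins, fams

    def test_charges_sum_to_total_weighted_field(self):
        grid, f, basins, fams = self._setup()
        charges = integrate_basins(basins, fams, f, grid)
        total = float((grid.weights * f.values).sum())
        assert sum(charges.values()) == pytest.approx(total, rel=1e-12)

    def test_isotropic_gaussian_integral_within_one_percent(self):
        # rho = exp(-r^2/2)/(2 pi)^(3/2) integrates to 1 analytically
        sigma = 1.0
        grid = make_grid("uniform", spacing=0.4, shape=(31, 31, 31),
                         origin=(-6.0, -6.0, -6.0))
        r2 = np.einsum("ij,ij->i", grid.points, grid.points)
        rho = np.exp(-r2 / (2 * sigma**2)) / (2 * np.pi * sigma**2) ** 1.5
        graph = build_delaunay(grid)
        basins = assign_basins_on_graph(graph, rho)
        fams = cluster_maxima_families(graph, rho, basins, t=0.25)
        charges = integrate_basins(basins, fams, rho, grid)
        assert fams.n_families == 1
        assert charges[0] == pytest.approx(1.0, rel=0.01)

    def test_promolecule_populations_recovered(self):
        centers = [(0.0, 0.0, -5.0), (0.0, 0.0, 5.0)]
        model = make_field("promolecule", centers=centers, populations=(2.0, 8.0),
                           exponents=(1.7, 2.2))
        grid = make_grid("atom_centered", centers=centers, n_radial=55, n_angular=194,
                         r_min=1e-4, r_max=9.0)
        graph = build_delaunay(grid)
        f = model.value(grid.points)
        basins = assign_basins_on_graph(graph, f)
        fams = cluster_maxima_families(graph, f, basins, t=0.25)
        charges = integrate_basins(basins, fams, f, grid)
        assert fams.n_families == 2
        got = sorted(charges.values())
        assert got[0] == pytest.approx(2.0, rel=0.01)
        assert got[1] == pytest.approx(8.0, rel=0.01)

    def test_missing_weights_with_fallback_disabled_raises(self):
        model = make_field("two_gaussian", a=(-1.0, 0.0), b=(1.0, 0.0))
        grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=200, seed=16, weights=None)
        graph = build_delaunay(grid)
        f = field_on_grid(model, grid)
        basins = assign_basins_on_graph(graph, f)
        fams = cluster_maxima_families(graph, f, basins, t=0.25)
        with pytest.raises(ValueError, match="weights"):
            integrate_basins(basins, fams, f, grid, voronoi_fallback=False)
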