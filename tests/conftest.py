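import numpy as np
import pytest

from gridtopo import Grid, build_delaunay, make_field, make_grid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture(scope="session")
def random_grid_2d():
    """400 uniform-random 2D points (no weights) with its Delaunay graph."""
    grid = make_grid("random", bounds=[(-3, 3), (-2, 2)], n=400, seed=11, weights=None)
    return grid, build_delaunay(grid)


@pytest.fixture(scope="session")
def two_gaussian_model():
    return make_field("two_gaussian", a=(-1.0, 0.0), b=(1.0, 0.0))


@pytest.fixture()
def tiny_grid_2d():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.1]])
    return Grid(pts)


def hexagon_fixture(seed=3, n=4000):
    """Six equal Gaussians on a hexagon (slightly jittered) on a random grid.

    Returns (grid, graph, values, vertex positions).  The aromatic-ring
    analogue: the critical tree can link at most 5 consecutive vertex
    pairs; gap-filling must restore the 6th.
    """
    from gridtopo import build_delaunay, make_field, make_grid

    rng = np.random.default_rng(seed)
    angles = np.pi / 3 * np.arange(6)
    centers = 2.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    centers += rng.normal(scale=0.01, size=centers.shape)  # break D6h ties
    model = make_field("gaussian_mixture", centers=centers, heights=1.0, widths=1.0)
    grid = make_grid("random", bounds=[(-3.5, 3.5), (-3.5, 3.5)], n=n, seed=seed, weights=None)
    graph = build_delaunay(grid)
    return grid, graph, model.value(grid.points), centers
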