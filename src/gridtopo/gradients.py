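"""Least-squares gradient estimation on neighborhood graphs.

At each node x the gradient g(x) of the sampled field is estimated by
minimizing the residual norm of a first-order Taylor expansion over the
neighbors y of x,

    sum_y | f(y) - f(x) - g . (y - x) |^2 ,

whose normal equations read M g = b with

    M = sum_y (y - x)(y - x)^T,     b = sum_y (y - x)(f(y) - f(x)).

On a basis-preserving node M has full rank and g is unique; where M is
rank-deficient (e.g. hull nodes with one-sided neighborhoods) the
minimum-norm solution restricted to the spanned subspace is returned and
the node is flagged in ``singular_mask`` rather than raising.

The residual norm is deliberately unweighted — a 1/|y-x|^2 distance
weighting is available behind ``distance_weight=True`` but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import NeighborhoodGraph
from .grids import Grid
from .transforms import field_values

__all__ = ["GradientField", "ls_gradient", "nn_gradient"]

#: relative eigenvalue cutoff below which a direction counts as unresolved
RCOND = 1e-10


@dataclass
class GradientField:
    """Per-node gradient vectors (field units per bohr) plus a singularity mask."""

    vectors: np.ndarray
    singular_mask: np.ndarray


def ls_gradient(
    graph: NeighborhoodGraph,
    values: np.ndarray,
    distance_weight: bool = False,
) -> GradientField:
    """Least-squares finite-difference gradient at every node.

    Parameters
    ----------
    graph : NeighborhoodGraph
    values : (n,) array
        Field values on the graph's grid.
    distance_weight : bool
        If True, weight each neighbor residual by 1/|y-x|^2.
    """
    f = field_values(values)
    n, d = graph.grid.points.shape
    if f.shape != (n,):
        raise ValueError(f"values shape {f.shape} does not match grid size {n}")
    src, dst = graph.directed_edges()
    dx = graph.grid.points[dst] - graph.grid.points[src]
    df = f[dst] - f[src]
    if distance_weight:
        w = 1.0 / np.einsum("ij,ij->i", dx, dx)
        dx_w = dx * w[:, None]
    else:
        dx_w = dx
    M = np.empty((n, d, d))
    b = np.empty((n, d))
    for a in range(d):
        b[:, a] = np.bincount(src, weights=dx_w[:, a] * df, minlength=n)
        for c in range(a, d):
            M[:, a, c] = np.bincount(src, weights=dx_w[:, a] * dx[:, c], minlength=n)
            M[:, c, a] = M[:, a, c]

    evals, evecs = np.linalg.eigh(M)
    cutoff = RCOND * evals[:, -1:].clip(min=1e-300)
    keep = evals > cutoff
    inv = np.where(keep, 1.0 / np.where(keep, evals, 1.0), 0.0)
    # pseudo-inverse restricted to the resolved subspace
    g = np.einsum("nij,nj,nkj,nk->ni", evecs, inv, evecs, b)
    singular = ~keep.all(axis=1)
    return GradientField(vectors=g, singular_mask=singular)


def nn_gradient(grid: Grid, gradients: GradientField, query: np.ndarray) -> np.ndarray:
    """Nearest-neighbor gradient field: g_NN(x) = g(nearest grid point of x).

    Piecewise constant over Voronoi cells; this is the field integrated by
    the off-graph ascent to correct grid bias.
    """
    idx = grid.nearest(query)
    return gradients.vectors[idx]
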