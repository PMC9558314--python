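"""Neighborhood graphs over point grids.

A neighborhood graph encodes, for every grid point, which other points
count as its neighbors.  All topographical notions used downstream (local
maxima, steepest ascent, critical paths) are defined relative to this
graph, so its construction determines how faithfully the topography of
the underlying continuous field survives discretization.

Two constructions are provided:

* ``build_delaunay`` — edges of the Delaunay triangulation.  Connected,
  undirected, and basis-/move-preserving on the bulk by construction;
  this is the recommended graph.
* ``build_knn`` — symmetrized k-nearest-neighbor graph.  Cheap, but may
  be disconnected and is generally *not* move-preserving; it is provided
  mainly to demonstrate the artifacts (fictitious extrema) such graphs
  introduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay, QhullError

from .grids import Grid

__all__ = [
    "NeighborhoodGraph",
    "GraphReport",
    "build_delaunay",
    "build_knn",
    "validate_graph",
    "nearest_grid_point",
]


@dataclass
class NeighborhoodGraph:
    """Undirected graph over grid indices, stored in CSR form.

    ``indptr``/``indices`` follow the scipy CSR convention: the neighbors
    of node ``i`` are ``indices[indptr[i]:indptr[i+1]]``, sorted
    ascending.  ``hull_mask`` flags nodes that are vertices of the convex
    hull H(G); the complement is the bulk B(G), on which the quality
    guarantees of a triangulation apply.
    """

    grid: Grid
    indptr: np.ndarray
    indices: np.ndarray
    hull_mask: np.ndarray
    construction: str
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.grid.n

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    @property
    def n_edges(self) -> int:
        return len(self.indices) // 2

    def edge_array(self) -> np.ndarray:
        """(m, 2) array of undirected edges with i < j, lexicographically sorted."""
        src = np.repeat(np.arange(self.n), self.degrees())
        mask = src < self.indices
        return np.column_stack([src[mask], self.indices[mask]])

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(source, target) arrays covering every adjacency entry once."""
        src = np.repeat(np.arange(self.n), self.degrees())
        return src, self.indices

    def to_sparse(self) -> sp.csr_matrix:
        data = np.ones(len(self.indices), dtype=np.int8)
        return sp.csr_matrix((data, self.indices, self.indptr), shape=(self.n, self.n))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edge_array()))
        return g


@dataclass
class GraphReport:
    """Diagnostic summary of the graph-quality conditions (bulk only)."""

    connected: bool
    undirected: bool
    basis_preserving_fraction: float
    move_preserving_fraction: float
    n_components: int
    n_bulk: int


def _csr_from_codes(n: int, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric CSR adjacency from undirected edge codes lo*n + hi.

    Deduplicates and symmetrizes in place-ish; kept lean because Delaunay
    edge lists at 1e6+ points dominate the pipeline's memory footprint.
    """
    codes = np.unique(codes)  # sorted unique undirected edges
    lo, hi = codes // n, codes % n
    both = np.empty(2 * len(codes), dtype=np.int64)
    both[: len(codes)] = lo * n + hi
    both[len(codes):] = hi * n + lo
    del codes
    both.sort()
    src, dst = both // n, both % n
    indptr = np.zeros(n + 1, dtype=np.int64)
    counts = np.bincount(src, minlength=n)
    np.cumsum(counts, out=indptr[1:])
    return indptr, dst


def _csr_from_pairs(n: int, pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric CSR adjacency from an (m, 2) array of undirected pairs."""
    if len(pairs) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.zeros(0, dtype=np.int64)
    pairs = np.asarray(pairs, dtype=np.int64)
    return _csr_from_codes(
        n, np.minimum(pairs[:, 0], pairs[:, 1]) * n + np.maximum(pairs[:, 0], pairs[:, 1])
    )


def build_delaunay(grid: Grid, jitter_seed: int = 0) -> NeighborhoodGraph:
    """Delaunay-triangulation neighborhood graph.

    Degenerate (cocircular/cospherical) configurations — ubiquitous for
    uniform lattices and spherical shells — are broken by a deterministic
    seeded jitter of magnitude 1e-9 x (bounding-box diagonal) applied to
    a copy of the points before triangulation.  The seed is recorded in
    the graph provenance, so construction is reproducible.
    """
    pts = grid.points
    n, d = pts.shape
    if d == 1:
        order = np.argsort(pts[:, 0], kind="stable")
        pairs = np.sort(np.column_stack([order[:-1], order[1:]]), axis=1)
        indptr, indices = _csr_from_pairs(n, pairs)
        hull = np.zeros(n, dtype=bool)
        hull[[order[0], order[-1]]] = True
        return NeighborhoodGraph(
            grid, indptr, indices, hull, "delaunay", {"jitter_seed": jitter_seed}
        )

    # escalate the jitter if Qhull's merge heuristics still fail: highly
    # structured grids (large cospherical shells) can defeat the smallest scale
    tri = None
    for magnitude in (1e-9, 1e-7, 1e-5):
        rng = np.random.default_rng(jitter_seed)
        jitter = rng.uniform(-1.0, 1.0, pts.shape) * (magnitude * grid.bbox_diagonal)
        try:
            tri = Delaunay(pts + jitter)
            break
        except QhullError as err:
            last_err = err
    if tri is None:
        raise ValueError(
            f"Delaunay triangulation failed (degenerate input): {last_err}"
        ) from last_err

    simplices = tri.simplices.astype(np.int64)
    hull_mask = np.zeros(n, dtype=bool)
    hull_mask[np.unique(tri.convex_hull)] = True
    del tri, jitter
    parts = []
    for i, j in zip(*np.triu_indices(d + 1, k=1)):
        a, b = simplices[:, i], simplices[:, j]
        parts.append(np.minimum(a, b) * n + np.maximum(a, b))
    del simplices
    indptr, indices = _csr_from_codes(n, np.concatenate(parts))
    return NeighborhoodGraph(
        grid, indptr, indices, hull_mask, "delaunay",
        {"jitter_seed": jitter_seed, "jitter_magnitude": magnitude},
    )


def build_knn(grid: Grid, k: int) -> NeighborhoodGraph:
    """Symmetrized k-nearest-neighbor graph.

    An edge (i, j) exists iff j is among the k nearest neighbors of i OR
    i is among the k nearest of j (the OR makes the graph undirected).
    Distance ties are broken by the lower point index.  The result may be
    disconnected and is not guaranteed to be move-preserving.
    """
    n = grid.n
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}, got {k}")
    m = min(k + 2, n)
    dist, idx = grid.tree.query(grid.points, k=m)
    pairs = []
    for i in range(n):
        di, ni = dist[i], idx[i]
        keep = ni != i
        di, ni = di[keep], ni[keep]
        order = np.lexsort((ni, np.round(di / max(di[-1], 1e-300), 12)))
        pairs.append(np.column_stack([np.full(k, i), ni[order][:k]]))
    pairs = np.vstack(pairs)
    pairs.sort(axis=1)
    indptr, indices = _csr_from_pairs(n, pairs)
    hull_mask = _hull_mask(grid)
    return NeighborhoodGraph(grid, indptr, indices, hull_mask, f"knn({k})")


def _hull_mask(grid: Grid) -> np.ndarray:
    mask = np.zeros(grid.n, dtype=bool)
    if grid.dim == 1:
        x = grid.points[:, 0]
        mask[np.argmin(x)] = True
        mask[np.argmax(x)] = True
        return mask
    hull = ConvexHull(grid.points)
    mask[hull.vertices] = True
    return mask


def _move_preserving(vectors: np.ndarray, d: int) -> bool:
    """True iff the origin lies strictly inside conv of the unit step vectors.

    Equivalent to condition 4: for every direction delta some neighbor move
    has positive projection onto delta.
    """
    norms = np.linalg.norm(vectors, axis=1)
    u = vectors[norms > 0] / norms[norms > 0, None]
    if len(u) < d + 1:
        return False
    if d == 1:
        return u.min() < 0 < u.max()
    try:
        hull = ConvexHull(u)
    except QhullError:
        return False  # directions degenerate: all in a lower-dimensional set
    # facet equations A x + b <= 0; origin strictly inside iff all b < 0
    return bool(np.all(hull.equations[:, -1] < -1e-10))


def validate_graph(graph: NeighborhoodGraph) -> GraphReport:
    """Check the four graph-quality conditions; never raises.

    Connectivity and undirectedness are global; the basis-preserving and
    move-preserving tests are evaluated per bulk node and reported as
    fractions over the bulk.  A Delaunay graph scores 1.0 on both.
    """
    adj = graph.to_sparse()
    n_comp, _ = connected_components(adj, directed=False)
    undirected = (adj != adj.T).nnz == 0
    pts = graph.grid.points
    d = graph.grid.dim
    bulk = np.flatnonzero(~graph.hull_mask)
    basis_ok = move_ok = 0
    for i in bulk:
        vecs = pts[graph.neighbors(i)] - pts[i]
        scale = np.abs(vecs).max() if len(vecs) else 0.0
        if scale > 0 and np.linalg.matrix_rank(vecs, tol=1e-10 * scale) == d:
            basis_ok += 1
            if _move_preserving(vecs, d):
                move_ok += 1
    nb = max(len(bulk), 1)
    return GraphReport(
        connected=n_comp == 1,
        undirected=bool(undirected),
        basis_preserving_fraction=basis_ok / nb,
        move_preserving_fraction=move_ok / nb,
        n_components=int(n_comp),
        n_bulk=len(bulk),
    )


def nearest_grid_point(grid: Grid, query: np.ndarray) -> int | np.ndarray:
    """Nearest grid point to ``query`` (KD-tree; ties to the lowest index)."""
    return grid.nearest(query)
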