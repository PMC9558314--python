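"""Point grids in 1-3 dimensions.

A :class:`Grid` is the fundamental container of the package: a set of
distinct points in real space (coordinates in bohr), optionally carrying
per-point integration weights (bohr^d).  Everything downstream — the
neighborhood graph, scalar fields, basins, critical networks — is indexed
by position in ``grid.points``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection, cKDTree

__all__ = ["Grid", "voronoi_volumes"]

#: points closer than this (bohr, per coordinate) are considered duplicates
DEDUP_DECIMALS = 12


@dataclass
class Grid:
    """A set of distinct points with optional integration weights.

    Parameters
    ----------
    points : (n, d) array
        Coordinates in bohr, d in {1, 2, 3}.  1D input may be passed as a
        flat array.  Duplicate points (equal to 1e-12 bohr) are merged and
        their weights summed.
    weights : (n,) array, optional
        Nonnegative integration weights in bohr^d.
    """

    points: np.ndarray
    weights: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim == 1:
            pts = pts[:, None]
        if pts.ndim != 2 or pts.shape[1] not in (1, 2, 3):
            raise ValueError(f"points must be (n, d) with d in 1..3, got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points contain non-finite values")
        w = None
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(pts),):
                raise ValueError(f"weights shape {w.shape} does not match {len(pts)} points")
            if np.any(w < 0):
                raise ValueError("weights must be nonnegative")
        pts, w = _deduplicate(pts, w)
        if len(pts) <= pts.shape[1]:
            raise ValueError(
                f"need at least d+1 = {pts.shape[1] + 1} distinct points, got {len(pts)}"
            )
        _check_affine_rank(pts)
        self.points = pts
        self.weights = w
        self._tree: cKDTree | None = None

    @property
    def n(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def bbox_diagonal(self) -> float:
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.linalg.norm(span))

    @property
    def tree(self) -> cKDTree:
        """KD-tree over the points (built lazily, cached)."""
        if self._tree is None:
            self._tree = cKDTree(self.points)
        return self._tree

    def nearest(self, query: np.ndarray) -> int | np.ndarray:
        """Index of the nearest grid point; ties go to the lowest index.

        Accepts a single d-vector or an (m, d) batch.
        """
        arr = np.asarray(query, dtype=float)
        single = arr.ndim == 1
        q = np.atleast_2d(arr)
        if q.shape[1] != self.dim:
            raise ValueError(f"query dimension {q.shape[1]} != grid dimension {self.dim}")
        k = min(4, self.n)
        dist, idx = self.tree.query(q, k=k)
        if k == 1:
            dist, idx = dist[:, None], idx[:, None]
        # resolve near-exact ties deterministically: lowest index wins
        tied = dist <= dist[:, :1] * (1 + 1e-12) + 1e-300
        out = np.where(tied, idx, self.n).min(axis=1)
        return int(out[0]) if single else out


def _deduplicate(pts: np.ndarray, w: np.ndarray | None):
    keys = np.round(pts, DEDUP_DECIMALS)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    if len(first) == len(pts):
        return pts, w
    warnings.warn(f"merged {len(pts) - len(first)} duplicate grid point(s)", stacklevel=3)
    order = np.argsort(first)  # keep first-occurrence order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_pts = pts[np.sort(first)]
    new_w = None
    if w is not None:
        new_w = np.zeros(len(first))
        np.add.at(new_w, rank[inverse], w)
    return new_pts, new_w


def _check_affine_rank(pts: np.ndarray) -> None:
    d = pts.shape[1]
    centered = pts - pts.mean(axis=0)
    scale = np.abs(centered).max()
    if scale == 0:
        raise ValueError("all points coincide")
    rank = np.linalg.matrix_rank(centered, tol=1e-10 * scale)
    if rank < d:
        raise ValueError(
            f"points are affinely degenerate: rank {rank} < dimension {d} "
            "(represent the data in a lower-dimensional grid instead)"
        )


def voronoi_volumes(grid: Grid) -> np.ndarray:
    """Volume of each point's Voronoi cell, clipped to the convex hull.

    These serve as fallback integration weights when a grid carries none;
    for a space-filling point set the cell volumes form a partition of the
    hull volume.  Cells are computed as halfspace intersections of the
    point's Delaunay-neighbor bisectors with the hull facets.
    """
    pts = grid.points
    n, d = pts.shape
    if d == 1:
        x = pts[:, 0]
        order = np.argsort(x)
        xs = x[order]
        mids = (xs[1:] + xs[:-1]) / 2
        lo = np.concatenate([[xs[0]], mids])
        hi = np.concatenate([mids, [xs[-1]]])
        vols = np.empty(n)
        vols[order] = hi - lo
        return vols

    from scipy.spatial import Delaunay  # local import to avoid cycle at module load

    tri = Delaunay(pts)
    indptr, indices = tri.vertex_neighbor_vertices
    hull = ConvexHull(pts)
    hull_eqs = hull.equations  # A x + b <= 0 inside
    centroid = pts.mean(axis=0)
    eps = 1e-9 * grid.bbox_diagonal
    vols = np.empty(n)
    for i in range(n):
        nbrs = indices[indptr[i] : indptr[i + 1]]
        mid = (pts[nbrs] + pts[i]) / 2
        normal = pts[nbrs] - pts[i]
        offs = -(normal * mid).sum(axis=1)
        halfspaces = np.vstack(
            [np.hstack([normal, offs[:, None]]), hull_eqs]
        )
        interior = pts[i] + (centroid - pts[i]) * (eps / max(np.linalg.norm(centroid - pts[i]), eps))
        try:
            hs = HalfspaceIntersection(halfspaces, interior)
            vols[i] = ConvexHull(hs.intersections).volume
        except Exception:
            # sliver cell: nudge further toward the centroid and retry once
            interior = pts[i] + 1e-4 * (centroid - pts[i])
            hs = HalfspaceIntersection(halfspaces, interior)
            vols[i] = ConvexHull(hs.intersections).volume
    return vols
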