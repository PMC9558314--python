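"""Basins of attraction, maxima families, and basin integration.

Every grid node is assigned to the graph local maximum its steepest-ascent
path terminates at.  Two ascent methods are provided:

* **on-graph** — the classic grid-ascent: from each node repeatedly step
  to the neighbor maximizing the slope (f(y) - f(x))/|y - x|, with path
  shortcutting (a path that hits an already-assigned node adopts its
  attractor).  Fast and deterministic, but suffers *grid bias*: ascent
  directions are restricted to graph edges, so basin boundaries are
  systematically distorted, an error that survives the infinite-density
  limit.
* **off-graph** — bias-corrected: trajectories move freely in space,
  integrating the piecewise-constant nearest-neighbor gradient field
  g_NN with a fixed step adapted to the local edge length, until they
  enter the Voronoi cell of a local maximum or of an already-assigned
  node.

Local maxima are then clustered into *maxima families* via overlapping
flood fills controlled by the scale-free deviation measure

    d(x, y) = (f(x) - f(y)) / (f(x) - f_min) in [0, 1],

so that spatially extended maxima (rings, shells, isosurfaces) are
recognized as a single family.  Basin integration accumulates
w(x) * rho(x) over each family's basin, yielding e.g. Bader charges.

Determinism: all ties are broken by the total order (f value, then lower
node index).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from numba import njit

from .gradients import GradientField, nn_gradient
from .graphs import NeighborhoodGraph
from .grids import Grid, voronoi_volumes
from .transforms import field_values

__all__ = [
    "BasinAssignment",
    "MaximaFamilies",
    "local_maxima",
    "assign_basins_on_graph",
    "assign_basins_off_graph",
    "cluster_maxima_families",
    "integrate_basins",
]

logger = logging.getLogger(__name__)


@dataclass
class BasinAssignment:
    """Map from every node to the local maximum whose basin it belongs to."""

    attractor: np.ndarray  # (n,) node index of each node's local maximum
    local_maxima: np.ndarray  # sorted node indices of the attractor set
    method: str  # "on_graph" | "off_graph"

    def basin_of(self, maximum: int) -> np.ndarray:
        return np.flatnonzero(self.attractor == maximum)


@dataclass
class MaximaFamilies:
    """Partition of the local maxima into families of one extended maximum each.

    Family ids are 0-based, ordered by descending field value of the
    family's highest maximum (ties: lower node index), so numbering is
    stable across runs.
    """

    family_of: dict  # local-maximum node index -> family id
    families: list  # family id -> sorted array of maxima node indices
    tolerance: float
    flood_fills: list = dataclass_field(default_factory=list)  # family id -> node array

    @property
    def n_families(self) -> int:
        return len(self.families)

    def family_of_node(self, basins: BasinAssignment) -> np.ndarray:
        """Per-node family id via each node's attractor."""
        lookup = np.full(int(max(self.family_of) + 1), -1, dtype=np.int64)
        for m, fam in self.family_of.items():
            lookup[m] = fam
        return lookup[basins.attractor]


def _totally_greater(f: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """True where node j is greater than node i in the (f, lower index) total order."""
    return (f[j] > f[i]) | ((f[j] == f[i]) & (j < i))


def local_maxima(graph: NeighborhoodGraph, field) -> np.ndarray:
    """Nodes strictly greater than all their neighbors, ascending by index.

    Strict inequality is used, so a constant field has no local maxima.
    """
    f = field_values(field)
    src, dst = graph.directed_edges()
    n_ge = np.bincount(src, weights=(f[dst] >= f[src]), minlength=graph.n)
    return np.flatnonzero(n_ge == 0)


def _steepest_successor(graph: NeighborhoodGraph, f: np.ndarray):
    """Per node: the steepest-ascent neighbor, or -1 for ascent terminals.

    The successor maximizes (f(y) - f(x))/|y - x| over neighbors y; ties
    are broken toward the neighbor greatest in the (f, lower index) total
    order.  A node is a terminal iff no neighbor is greater than it in
    that order (for generic fields: exactly the strict local maxima).
    """
    n = graph.n
    src, dst = graph.directed_edges()
    pts = graph.grid.points
    dist = np.linalg.norm(pts[dst] - pts[src], axis=1)
    slope = (f[dst] - f[src]) / dist
    greater = _totally_greater(f, src, dst)
    # lexsort: per source node take max slope, ties -> max f[dst], then min dst
    order = np.lexsort((dst, -f[dst], -slope, src))
    s, d = src[order], dst[order]
    first = np.zeros(len(s), dtype=bool)
    if len(s):
        first[0] = True
        first[1:] = s[1:] != s[:-1]
    successor = np.full(n, -1, dtype=np.int64)
    successor[s[first]] = d[first]
    # terminals: no totally-greater neighbor at all
    has_greater = np.bincount(src, weights=greater, minlength=n) > 0
    successor[~has_greater] = -1
    return successor


def assign_basins_on_graph(graph: NeighborhoodGraph, field) -> BasinAssignment:
    """Steepest-ascent basin assignment constrained to graph edges.

    Equivalent to tracing the full ascent path from every node (the
    shortcut through already-assigned nodes changes cost, not results);
    implemented as pointer-jumping on the successor map.
    """
    f = field_values(field)
    if len(local_maxima(graph, f)) == 0:
        raise ValueError("field has no graph local maxima")
    successor = _steepest_successor(graph, f)
    terminals = successor < 0
    attractor = np.where(terminals, np.arange(graph.n), successor)
    # pointer jumping: successor chains strictly ascend the total order,
    # so O(log(path length)) rounds converge
    while True:
        nxt = attractor[attractor]
        if np.array_equal(nxt, attractor):
            break
        attractor = nxt
    return BasinAssignment(
        attractor=attractor,
        local_maxima=np.flatnonzero(terminals),
        method="on_graph",
    )


def assign_basins_off_graph(
    graph: NeighborhoodGraph,
    field,
    gradients: GradientField,
    step_scale: float = 0.5,
    step_cap: int | None = None,
) -> BasinAssignment:
    """Bias-corrected basin assignment following the off-graph gradient.

    From each node a trajectory moves freely in space with steps of
    ``step_scale`` x (median incident edge length of the current nearest
    node) along g_NN, until it enters the Voronoi cell of a local maximum
    or of a node whose attractor is already known.  Trajectories that
    exhaust the step cap (default 10 * n^(1/d)) fall back to on-graph
    ascent from their seed, with a warning.
    """
    f = field_values(field)
    grid = graph.grid
    n, d = grid.points.shape
    maxima = local_maxima(graph, f)
    if len(maxima) == 0:
        raise ValueError("field has no graph local maxima")
    if step_cap is None:
        step_cap = int(10 * n ** (1.0 / d)) + 10

    # median incident edge length per node -> local step size
    src, dst = graph.directed_edges()
    elen = np.linalg.norm(grid.points[dst] - grid.points[src], axis=1)
    step_len = np.empty(n)
    for i in range(n):  # degrees are small; this is O(edges)
        step_len[i] = np.median(elen[graph.indptr[i] : graph.indptr[i + 1]])
    step_len *= step_scale

    attractor = np.full(n, -1, dtype=np.int64)
    attractor[maxima] = maxima
    is_max = np.zeros(n, dtype=bool)
    is_max[maxima] = True

    seeds = np.flatnonzero(~is_max)
    pos = grid.points[seeds].copy()
    active = np.ones(len(seeds), dtype=bool)
    g = gradients.vectors
    gnorm = np.linalg.norm(g, axis=1)
    stuck_seeds = []

    for _ in range(step_cap):
        if not active.any():
            break
        ai = np.flatnonzero(active)
        nearest = grid.tree.query(pos[ai], k=1)[1]
        known = attractor[nearest] >= 0
        if known.any():
            attractor[seeds[ai[known]]] = attractor[nearest[known]]
            active[ai[known]] = False
            ai = ai[~known]
            nearest = nearest[~known]
            if len(ai) == 0:
                continue
        flat = gnorm[nearest] <= 0
        if flat.any():
            stuck_seeds.extend(seeds[ai[flat]])
            active[ai[flat]] = False
            ai, nearest = ai[~flat], nearest[~flat]
            if len(ai) == 0:
                continue
        pos[ai] += (step_len[nearest] / gnorm[nearest])[:, None] * g[nearest]

    leftover = np.concatenate([seeds[active], np.asarray(stuck_seeds, dtype=np.int64)])
    if len(leftover):
        warnings.warn(
            f"off-graph ascent fell back to on-graph for {len(leftover)} node(s) "
            "(step cap exhausted or vanishing gradient)",
            stacklevel=2,
        )
        on = assign_basins_on_graph(graph, f)
        attractor[leftover] = on.attractor[leftover]
    return BasinAssignment(attractor=attractor, local_maxima=maxima, method="off_graph")


@njit(cache=True)
def _uf_find(parent, a):
    while parent[a] != a:
        parent[a] = parent[parent[a]]
        a = parent[a]
    return a


@njit(cache=True)
def _family_sweep(order, indptr, indices, f, max_id, tau, n_max):
    """Merge-tree sweep computing which maxima have overlapping flood fills.

    Nodes are visited in descending (f, lower-index) order; components of
    the superlevel graph are tracked with union-find.  Two maxima's fills
    overlap exactly when their components join at a level L above the
    smaller of their fill thresholds tau = (1-t) f(max) + t f_min, so one
    sweep reproduces the transitive fill merging without materializing a
    single fill.  Returns the union-find parent array over maxima ids.
    """
    n = len(order)
    comp = np.full(n, -1, dtype=np.int64)
    fam = np.arange(n_max, dtype=np.int64)
    tau_fam = tau.copy()
    # per component root: its open family (-1 if none; a component can hold
    # at most one family still below its fill threshold) and a linked list
    # of every family root living in the component
    open_fam = np.full(n, -1, dtype=np.int64)
    head = np.full(n, -1, dtype=np.int64)
    tail = np.full(n, -1, dtype=np.int64)
    nxt = np.full(max(n_max, 1), -1, dtype=np.int64)

    for i in range(n):
        y = order[i]
        comp[y] = y
        m = max_id[y]
        if m >= 0:
            open_fam[y] = m
            head[y] = m
            tail[y] = m
        L = f[y]
        for k in range(indptr[y], indptr[y + 1]):
            z = indices[k]
            if comp[z] < 0:
                continue
            rz = _uf_find(comp, z)
            ry = _uf_find(comp, y)
            if rz == ry:
                continue
            ox = open_fam[ry]
            if ox >= 0:
                ox = _uf_find(fam, ox)
                if not tau_fam[ox] < L:
                    ox = -1
            oy = open_fam[rz]
            if oy >= 0:
                oy = _uf_find(fam, oy)
                if not tau_fam[oy] < L:
                    oy = -1
            if ox >= 0 and oy >= 0:
                # an open family on each side: every maximum of both
                # components belongs to one family now
                for start in (head[ry], head[rz]):
                    g = start
                    while g >= 0:
                        rg = _uf_find(fam, g)
                        rt = _uf_find(fam, ox)
                        if rg != rt:
                            fam[rg] = rt
                            if tau_fam[rg] < tau_fam[rt]:
                                tau_fam[rt] = tau_fam[rg]
                        g = nxt[g]
                merged_head = _uf_find(fam, ox)
                merged_tail = merged_head
                nxt[merged_head] = -1
                new_open = merged_head
            elif ox >= 0 or oy >= 0:
                # one side open: the other side's families all join it
                target = ox if ox >= 0 else oy
                other = rz if ox >= 0 else ry
                keeper = ry if ox >= 0 else rz
                g = head[other]
                while g >= 0:
                    rg = _uf_find(fam, g)
                    rt = _uf_find(fam, target)
                    if rg != rt:
                        fam[rg] = rt
                        if tau_fam[rg] < tau_fam[rt]:
                            tau_fam[rt] = tau_fam[rg]
                    g = nxt[g]
                merged_head = head[keeper]
                merged_tail = tail[keeper]
                new_open = _uf_find(fam, target)
            else:
                # both closed: concatenate lists, nothing merges
                if head[ry] < 0:
                    merged_head, merged_tail = head[rz], tail[rz]
                elif head[rz] < 0:
                    merged_head, merged_tail = head[ry], tail[ry]
                else:
                    nxt[tail[ry]] = head[rz]
                    merged_head, merged_tail = head[ry], tail[rz]
                new_open = -1
            comp[rz] = ry
            open_fam[ry] = new_open
            head[ry] = merged_head
            tail[ry] = merged_tail
    return fam


@njit(cache=True)
def _family_coverage(indptr, indices, f, seeds, thresholds, labels):
    """Label nodes reachable from seed k through nodes with f > thresholds[k].

    A family's coverage equals the superlevel component of its loosest
    member at that member's threshold; coverages of distinct families are
    pairwise disjoint (a shared node would have merged them), so one
    multi-source flood is conflict-free.
    """
    n = len(labels)
    stack = np.empty(n, dtype=np.int64)
    for k in range(len(seeds)):
        s = seeds[k]
        th = thresholds[k]
        labels[s] = k
        top = 0
        stack[top] = s
        top += 1
        while top > 0:
            top -= 1
            x = stack[top]
            for j in range(indptr[x], indptr[x + 1]):
                y = indices[j]
                if labels[y] < 0 and f[y] > th:
                    labels[y] = k
                    stack[top] = y
                    top += 1


def flood_fill_families_reference(graph, field, maxima, t):
    """Literal per-maximum flood fill + transitive merging (reference oracle).

    O(n_maxima x fill size); used to validate the sweep implementation on
    small inputs.  Returns ({family root: member list}, {family root: set
    of covered nodes}).
    """
    f = field_values(field)
    f_min = f.min()
    ms = [int(m) for m in maxima]
    parent = {m: m for m in ms}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    fills = {}
    for m in ms:
        scale = f[m] - f_min
        fill = {m}
        frontier = [m]
        while frontier:
            new = []
            for x in frontier:
                for y in graph.neighbors(x):
                    y = int(y)
                    if y in fill:
                        continue
                    dev = (f[m] - f[y]) / scale if scale > 0 else 0.0
                    if dev < t:
                        fill.add(y)
                        new.append(y)
            frontier = new
        fills[m] = fill
    for i, a in enumerate(ms):
        for b in ms[i + 1:]:
            if fills[a] & fills[b]:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    groups: dict = {}
    for m in ms:
        groups.setdefault(find(m), []).append(m)
    covers = {r: set().union(*(fills[m] for m in members))
              for r, members in groups.items()}
    return groups, covers


def cluster_maxima_families(
    graph: NeighborhoodGraph,
    field,
    basins: BasinAssignment,
    t: float = 0.25,
) -> MaximaFamilies:
    """Cluster local maxima into families by merging overlapping flood fills.

    Around each local maximum x, a flood fill covers every node y with
    deviation d(x, y) = (f(x) - f(y))/(f(x) - f_min) < t (f_min = global
    minimum value) reachable through such nodes; fills sharing a node
    merge transitively and the merged groups are the maxima families.
    Implemented as a descending merge-tree sweep -- two fills overlap
    exactly when the maxima's superlevel components join above the looser
    fill threshold -- because dense atom-centered grids carry thousands of
    near-degenerate maxima whose literal fills each span a large ball.
    """
    if not 0 < t <= 1:
        raise ValueError(f"family tolerance t must be in (0, 1], got {t}")
    f = field_values(field)
    f_min = float(f.min())
    maxima = np.asarray(basins.local_maxima, dtype=np.int64)
    n_max = len(maxima)

    # fill threshold per maximum; a flat field fills everywhere
    scale = f[maxima] - f_min
    tau = np.where(scale > 0, (1 - t) * f[maxima] + t * f_min, -np.inf)
    max_id = np.full(graph.n, -1, dtype=np.int64)
    max_id[maxima] = np.arange(n_max)
    order = np.lexsort((np.arange(graph.n), -f)).astype(np.int64)
    fam = _family_sweep(order, graph.indptr, graph.indices, f, max_id, tau, n_max)

    groups: dict[int, list[int]] = {}
    for k in range(n_max):
        groups.setdefault(int(_uf_find(fam, k)), []).append(int(maxima[k]))
    # stable family order: descending max f, then lower node index
    reps = sorted(
        groups,
        key=lambda r: (-max(f[groups[r]]), min(g for g in groups[r] if f[g] == max(f[groups[r]]))),
    )
    family_of = {}
    families = []
    seeds = []
    thresholds = []
    for fam_id, r in enumerate(reps):
        members = np.array(sorted(groups[r]), dtype=np.int64)
        families.append(members)
        for m in members:
            family_of[int(m)] = fam_id
        k_loosest = int(np.argmin(tau[max_id[members]]))
        seeds.append(int(members[k_loosest]))
        thresholds.append(float(tau[max_id[members]].min()))
    labels = np.full(graph.n, -1, dtype=np.int64)
    if seeds:
        _family_coverage(graph.indptr, graph.indices, f,
                         np.asarray(seeds, dtype=np.int64),
                         np.asarray(thresholds, dtype=float), labels)
    flood_fills = [np.flatnonzero(labels == fam_id) for fam_id in range(len(families))]
    return MaximaFamilies(
        family_of=family_of, families=families, tolerance=t, flood_fills=flood_fills
    )



def integrate_basins(
    basins: BasinAssignment,
    families: MaximaFamilies,
    integrand,
    grid: Grid,
    voronoi_fallback: bool = True,
) -> dict[int, float]:
    """Accumulate Q_M = sum over the basin of family M of w(x) * rho(x).

    ``integrand`` may differ from the field used for basin assignment
    (e.g. integrate a kinetic-energy density over electron-density
    basins).  If the grid carries no weights, Voronoi cell volumes
    (clipped to the convex hull) are used when ``voronoi_fallback`` is
    enabled; otherwise an error is raised.
    """
    rho = field_values(integrand)
    if grid.weights is not None:
        w = grid.weights
    elif voronoi_fallback:
        logger.info("grid has no weights; computing Voronoi cell volumes")
        w = voronoi_volumes(grid)
    else:
        raise ValueError("grid has no integration weights and Voronoi fallback is disabled")
    fam = families.family_of_node(basins)
    q = np.bincount(fam, weights=w * rho, minlength=families.n_families)
    return {int(i): float(q[i]) for i in range(families.n_families)}
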