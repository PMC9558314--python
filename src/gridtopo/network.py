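"""Critical paths, critical points, and the critical network.

A *critical path* between two graph local maxima is the path maximizing
the minimum field value encountered (the path's *critical value*); its
minimum-value node plays the role of a first-order saddle (for the
electron density: a bond critical point).  With edge weights
w(i, j) = (f(i) + f(j))/2 this is the classic widest-path problem, whose
solutions all live on the maximum spanning tree (MST).  The pipeline is:

1. ``max_spanning_tree``        — Kruskal on descending edge weight,
   ties broken lexicographically by edge index (deterministic on
   symmetric fields).
2. ``prune_to_critical_tree``   — iteratively strip non-maximum leaves;
   what remains is exactly the union of all critical paths, and per
   maxima pair the minimum node on the connecting path is recorded as a
   critical point.
3. ``gap_fill``                 — the tree is acyclic, so cycles of
   near-equal critical value (aromatic rings!) lose one link; adjacent
   basin pairs are re-examined on their two-basin subgraph and the
   missing link restored when its path stays clear of the subgraph
   boundary.
4. ``cleave``                   — optionally cut paths along which the
   field deviates strongly from the endpoint maxima, leaving the flat
   sub-trees (used for stagnation graphs of -|J|).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
from numba import njit

from .graphs import NeighborhoodGraph
from .transforms import field_values

__all__ = [
    "CriticalNetwork",
    "max_spanning_tree",
    "prune_to_critical_tree",
    "gap_fill",
    "cleave",
]


@dataclass
class CriticalNetwork:
    """Union of critical paths with their critical points.

    ``edges`` are undirected node pairs (i < j).  ``paths`` maps each
    critically linked maxima pair (x, y), x < y, to the ordered node
    sequence of its path; ``critical_points`` maps the same pair to
    (node, value) of the path minimum.  ``filled_edges`` is the subset of
    edges contributed by gap-filling (disjoint from the pruned tree).
    """

    edges: set
    maxima: np.ndarray
    paths: dict
    critical_points: dict
    filled_edges: set = dataclass_field(default_factory=set)
    provenance: dict = dataclass_field(default_factory=dict)

    @property
    def nodes(self) -> np.ndarray:
        out = set()
        for e in self.edges:
            out.update(e)
        out.update(int(m) for m in self.maxima)
        return np.array(sorted(out), dtype=np.int64)

    def n_components(self) -> int:
        import networkx as nx

        g = nx.Graph(list(self.edges))
        g.add_nodes_from(int(m) for m in self.maxima)
        return nx.number_connected_components(g)


@njit(cache=True)
def _kruskal(n, src, dst):
    """Union-find Kruskal over edges already sorted by priority."""
    parent = np.arange(n, dtype=np.int64)
    chosen = np.zeros(len(src), dtype=np.bool_)
    n_join = 0
    for e in range(len(src)):
        a, b = src[e], dst[e]
        ra = a
        while parent[ra] != ra:
            parent[ra] = parent[parent[ra]]
            ra = parent[ra]
        rb = b
        while parent[rb] != rb:
            parent[rb] = parent[parent[rb]]
            rb = parent[rb]
        if ra != rb:
            parent[rb] = ra
            chosen[e] = True
            n_join += 1
    return chosen, n_join


def _mst_edges(n: int, src: np.ndarray, dst: np.ndarray, w: np.ndarray):
    """Maximum spanning forest edges; ties by lexicographic (i, j)."""
    order = np.lexsort((dst, src, -w))
    chosen, n_join = _kruskal(n, src[order].astype(np.int64), dst[order].astype(np.int64))
    sel = order[chosen]
    return np.column_stack([src[sel], dst[sel]]), n_join


def max_spanning_tree(graph: NeighborhoodGraph, field) -> np.ndarray:
    """Maximum spanning tree under w(i, j) = (f(i) + f(j))/2.

    Returns an (n-1, 2) edge array (i < j).  Raises on a disconnected
    graph, reporting the component count.
    """
    f = field_values(field)
    edges = graph.edge_array()
    src, dst = edges[:, 0], edges[:, 1]
    w = (f[src] + f[dst]) / 2.0
    tree, n_join = _mst_edges(graph.n, src, dst, w)
    if n_join != graph.n - 1:
        n_comp = graph.n - n_join
        raise ValueError(f"graph is disconnected ({n_comp} components); cannot span")
    return tree


@njit(cache=True)
def _prune(indptr, indices, is_max):
    """Queue-based removal of non-maximum leaves; returns alive mask."""
    n = len(indptr) - 1
    degree = np.zeros(n, dtype=np.int64)
    for i in range(n):
        degree[i] = indptr[i + 1] - indptr[i]
    alive = np.ones(n, dtype=np.bool_)
    stack = np.empty(n, dtype=np.int64)
    top = 0
    for i in range(n):
        if degree[i] <= 1 and not is_max[i]:
            stack[top] = i
            top += 1
    while top > 0:
        top -= 1
        i = stack[top]
        if not alive[i] or is_max[i] or degree[i] > 1:
            continue
        alive[i] = False
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            if alive[j]:
                degree[j] -= 1
                if degree[j] <= 1 and not is_max[j]:
                    stack[top] = j
                    top += 1
    return alive


def _tree_csr(n: int, edges: np.ndarray):
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.argsort(src, kind="stable")
    src, dst = src[order], dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, dst


def _collect_paths(indptr, indices, alive, maxima, f):
    """Walk the pruned tree and record maxima-free paths between maxima.

    Returns (paths, critical_points) keyed by (x, y) with x < y.  Only
    pairs whose connecting path contains no third maximum are critical
    pairs.
    """
    is_max = np.zeros(len(alive), dtype=bool)
    is_max[maxima] = True
    paths: dict = {}
    cps: dict = {}
    for m in maxima:
        m = int(m)
        # DFS from m through non-maximum alive nodes
        stack = [(m, -1)]
        parent = {m: -1}
        while stack:
            x, par = stack.pop()
            for y in indices[indptr[x] : indptr[x + 1]]:
                y = int(y)
                if y == par or not alive[y]:
                    continue
                if y in parent:
                    continue
                parent[y] = x
                if is_max[y]:
                    if m < y:  # record each pair once
                        path = [y]
                        z = x
                        while z != -1:
                            path.append(z)
                            z = parent[z]
                        path.reverse()  # runs m .. y
                        arr = np.array(path, dtype=np.int64)
                        paths[(m, y)] = arr
                        k = int(np.argmin(f[arr]))
                        cps[(m, y)] = (int(arr[k]), float(f[arr[k]]))
                else:
                    stack.append((y, x))
    return paths, cps


def prune_to_critical_tree(
    tree: np.ndarray, field, maxima: np.ndarray, n_nodes: int | None = None
) -> CriticalNetwork:
    """Strip non-maximum leaves from a spanning tree until only critical paths remain."""
    f = field_values(field)
    maxima = np.asarray(maxima, dtype=np.int64)
    if len(maxima) == 0:
        raise ValueError("maxima list is empty")
    n = n_nodes or len(f)
    indptr, indices = _tree_csr(n, np.asarray(tree, dtype=np.int64))
    is_max = np.zeros(n, dtype=bool)
    is_max[maxima] = True
    alive = _prune(indptr, indices, is_max)
    tree = np.asarray(tree, dtype=np.int64)
    keep_mask = alive[tree[:, 0]] & alive[tree[:, 1]]
    kept_arr = np.sort(tree[keep_mask], axis=1)
    kept = set(map(tuple, kept_arr.tolist()))
    paths, cps = _collect_paths(indptr, indices, alive, maxima, f)
    return CriticalNetwork(
        edges=kept,
        maxima=maxima,
        paths=paths,
        critical_points=cps,
        provenance={"pruned_tree": True, "gap_filled": False, "cleaved": False},
    )


def _network_path(network: CriticalNetwork, x: int, y: int):
    """BFS path x..y over the network's edge set (None if disconnected)."""
    adj: dict = {}
    for a, b in network.edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    if x not in adj or y not in adj:
        return None
    from collections import deque

    parent = {x: -1}
    dq = deque([x])
    while dq:
        z = dq.popleft()
        if z == y:
            path = [y]
            while parent[path[-1]] != -1:
                path.append(parent[path[-1]])
            return path[::-1]
        for w in adj[z]:
            if w not in parent:
                parent[w] = z
                dq.append(w)
    return None


def gap_fill(
    network: CriticalNetwork,
    graph: NeighborhoodGraph,
    field,
    basins,
) -> CriticalNetwork:
    """Restore cycle-closing critical links between adjacent basins.

    For every maxima pair not already linked (their path on the pruned
    tree crosses more than two basins): if the two basins share a graph
    edge, the maximum spanning tree of the two-basin subgraph is built
    and the path between the maxima added — unless that path touches the
    subgraph boundary, which marks the pair as not critically linked.
    Pairs are visited in ascending (x, y) order; fills are independent,
    so the order does not affect the result.
    """
    f = field_values(field)
    attractor = basins.attractor
    maxima = network.maxima
    src, dst = graph.directed_edges()
    edge_basin_src = attractor[src]
    edge_basin_dst = attractor[dst]
    adjacent_basins = set(
        zip(edge_basin_src.tolist(), edge_basin_dst.tolist())
    )

    edges = set(network.edges)
    filled = set(network.filled_edges)
    paths = dict(network.paths)
    cps = dict(network.critical_points)

    for ix in range(len(maxima)):
        for iy in range(ix + 1, len(maxima)):
            x, y = int(maxima[ix]), int(maxima[iy])
            tree_path = _network_path(network, x, y)
            if tree_path is not None:
                labels = {int(attractor[z]) for z in tree_path}
                if len(labels) <= 2:
                    continue  # already critically linked
            bx, by = int(attractor[x]), int(attractor[y])
            if bx == by or (bx, by) not in adjacent_basins:
                continue
            # two-basin subgraph
            in_sub = (attractor == bx) | (attractor == by)
            sub_mask = in_sub[src] & in_sub[dst]
            # boundary: subgraph nodes with a neighbor outside
            boundary = np.zeros(graph.n, dtype=bool)
            out_edges = in_sub[src] & ~in_sub[dst]
            if out_edges.any():
                boundary[np.unique(src[out_edges])] = True
            e_mask = sub_mask & (src < dst)
            s_sub, d_sub = src[e_mask], dst[e_mask]
            w_sub = (f[s_sub] + f[d_sub]) / 2.0
            sub_tree, _ = _mst_edges(graph.n, s_sub, d_sub, w_sub)
            sub_net = CriticalNetwork(
                edges={(int(min(a, b)), int(max(a, b))) for a, b in sub_tree},
                maxima=np.array([x, y]),
                paths={},
                critical_points={},
            )
            p = _network_path(sub_net, x, y)
            if p is None or any(boundary[z] for z in p):
                continue  # not critically linked
            arr = np.array(p, dtype=np.int64)
            new_edges = {
                (int(min(a, b)), int(max(a, b))) for a, b in zip(p[:-1], p[1:])
            }
            filled |= new_edges - edges
            edges |= new_edges
            key = (min(x, y), max(x, y))
            paths[key] = arr
            k = int(np.argmin(f[arr]))
            cps[key] = (int(arr[k]), float(f[arr[k]]))

    prov = dict(network.provenance)
    prov["gap_filled"] = True
    return CriticalNetwork(
        edges=edges,
        maxima=maxima,
        paths=paths,
        critical_points=cps,
        filled_edges=filled,
        provenance=prov,
    )


def _auto_flat_tolerance(deviations: np.ndarray) -> float:
    """First local minimum of a Gaussian KDE of the deviations; 0.1 if unimodal."""
    from scipy.stats import gaussian_kde

    devs = np.asarray(deviations, dtype=float)
    if len(devs) < 2 or np.ptp(devs) < 1e-12:
        return 0.1
    kde = gaussian_kde(devs, bw_method="scott")
    xs = np.linspace(devs.min(), devs.max(), 512)
    dens = kde(xs)
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])
    )
    if len(interior) == 0:
        return 0.1
    return float(xs[interior[0] + 1])


def cleave(
    network: CriticalNetwork,
    field,
    t_flat="auto",
    statistic: str = "min",
) -> CriticalNetwork:
    """Remove non-flat critical paths, keeping sub-trees of weak variation.

    Per path P(x, y): values are rescaled as
    s(z) = (f(z) - f_min)/(f_scale - f_min) with f_scale = max(f(x), f(y)),
    and the deviation is 1 - min_z s(z) (``statistic="mean"`` uses the
    mean of 1 - s instead).  Paths with deviation >= t_flat are cleaved.
    ``t_flat="auto"`` places the threshold at the first local minimum of
    a kernel density estimate of the deviation distribution (0.1 when
    unimodal).
    """
    f = field_values(field)
    f_min = float(f.min())
    devs = {}
    for (x, y), path in network.paths.items():
        f_scale = max(f[x], f[y])
        if f_scale - f_min <= 0:
            devs[(x, y)] = 0.0
            continue
        s = (f[path] - f_min) / (f_scale - f_min)
        devs[(x, y)] = float(1 - s.min()) if statistic == "min" else float(np.mean(1 - s))
    if t_flat == "auto":
        t_flat = _auto_flat_tolerance(np.array(list(devs.values())))
    t_flat = float(t_flat)

    edges = set(network.edges)
    paths = {}
    cps = {}
    for (x, y), path in network.paths.items():
        if devs[(x, y)] >= t_flat:
            edges -= {
                (int(min(a, b)), int(max(a, b)))
                for a, b in zip(path[:-1], path[1:])
            }
        else:
            paths[(x, y)] = path
            cps[(x, y)] = network.critical_points.get((x, y))
    prov = dict(network.provenance)
    prov["cleaved"] = True
    prov["t_flat"] = t_flat
    prov["cleave_statistic"] = statistic
    return CriticalNetwork(
        edges=edges,
        maxima=network.maxima,
        paths=paths,
        critical_points=cps,
        filled_edges=set(network.filled_edges) & edges,
        provenance=prov,
    )
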