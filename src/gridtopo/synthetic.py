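"""Synthetic grids and analytic model fields with known topology.

Everything the analysis pipeline consumes can be generated here without
any electronic-structure calculation: uniform lattices, uniform-random
point clouds, and simplified atom-centered (radial x angular) quadrature
grids, together with closed-form model fields (Gaussian peaks, ring
maxima, promolecular densities, radial shell profiles, a model ring
current).  Each model carries its analytic gradient and a descriptor of
its known topology, so algorithmic results can be checked against ground
truth.

Atom-centered grids use geometric radial shells with midpoint-in-log
weights and deterministic golden-spiral sphere points; for multi-center
grids the product weights are multiplied by Becke partition-of-unity
cell functions so that overlapping atomic grids still integrate
correctly.  This is a deliberately simplified stand-in for production
DFT quadratures (LMG radial rules, Lebedev shells): positivity and
honest quadrature are what matter here, not optimal efficiency.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable

import numpy as np

from .grids import Grid, voronoi_volumes
from .transforms import ScalarField

__all__ = ["ModelField", "make_grid", "make_field", "field_on_grid", "fibonacci_sphere"]


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

def fibonacci_sphere(m: int, offset: float = 0.0) -> np.ndarray:
    """m quasi-uniform unit-sphere points on a golden spiral (deterministic)."""
    i = np.arange(m) + 0.5
    z = 1 - 2 * i / m
    phi = i * (np.pi * (3 - np.sqrt(5.0))) + offset
    r = np.sqrt(np.clip(1 - z * z, 0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _becke_weights(points: np.ndarray, centers: np.ndarray, which: np.ndarray) -> np.ndarray:
    """Becke partition-of-unity factor of each point's own center (3 iterations)."""
    dists = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2)
    nc = len(centers)
    cell = np.ones((len(points), nc))
    for a in range(nc):
        for b in range(nc):
            if a == b:
                continue
            mu = (dists[:, a] - dists[:, b]) / np.linalg.norm(centers[a] - centers[b])
            for _ in range(3):
                mu = 1.5 * mu - 0.5 * mu**3
            cell[:, a] *= 0.5 * (1 - mu)
    total = cell.sum(axis=1)
    return cell[np.arange(len(points)), which] / np.where(total > 0, total, 1.0)


def make_grid(kind: str, seed: int = 0, **params) -> Grid:
    """Generate a grid of one of three kinds (deterministic per seed).

    uniform
        ``origin`` (d,), ``spacing`` s, ``shape`` (n1..nd): lattice points
        origin + s*index with cell-volume weights s^d.
    random
        ``bounds`` ((lo, hi), ...), ``n``: uniform-random points;
        ``weights="voronoi"`` (default) attaches Voronoi cell volumes,
        ``weights=None`` attaches none.
    atom_centered
        ``centers`` (m, 3), ``n_radial``, ``n_angular``, ``r_min``,
        ``r_max``: per center, geometric radial shells times golden-spiral
        sphere points; weights are radial x angular quadrature products,
        Becke-partitioned for multiple centers.
    """
    if kind == "uniform":
        spacing = float(params["spacing"])
        shape = tuple(int(s) for s in params["shape"])
        if spacing <= 0 or any(s < 1 for s in shape):
            raise ValueError("uniform grid needs positive spacing and shape")
        origin = np.asarray(params.get("origin", np.zeros(len(shape))), dtype=float)
        axes = [origin[i] + spacing * np.arange(shape[i]) for i in range(len(shape))]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        w = np.full(len(pts), spacing ** len(shape))
        return Grid(pts, w, provenance={"kind": "uniform", "spacing": spacing, "shape": shape})

    if kind == "random":
        bounds = np.asarray(params["bounds"], dtype=float)
        n = int(params["n"])
        if n < bounds.shape[0] + 1:
            raise ValueError("random grid needs at least d+1 points")
        rng = np.random.default_rng(seed)
        pts = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n, bounds.shape[0]))
        grid = Grid(pts, provenance={"kind": "random", "seed": seed, "n": n})
        if params.get("weights", "voronoi") == "voronoi":
            grid.weights = voronoi_volumes(grid)
        return grid

    if kind == "atom_centered":
        centers = np.atleast_2d(np.asarray(params["centers"], dtype=float))
        n_rad = int(params["n_radial"])
        n_ang = int(params["n_angular"])
        r_min = float(params.get("r_min", 1e-4))
        r_max = float(params.get("r_max", 12.0))
        if n_rad < 2 or n_ang < 6 or not 0 < r_min < r_max:
            raise ValueError("invalid atom-centered grid parameters")
        h = np.log(r_max / r_min) / (n_rad - 1)
        radii = r_min * np.exp(h * np.arange(n_rad))
        w_rad = radii**3 * h  # int f r^2 dr = int f r^3 dlnr (midpoint in log r)
        golden = np.pi * (3 - np.sqrt(5.0))
        pts_all, w_all, owner = [], [], []
        for ic, c in enumerate(centers):
            for k, (r, wr) in enumerate(zip(radii, w_rad)):
                sphere = fibonacci_sphere(n_ang, offset=golden * (k + n_rad * ic))
                pts_all.append(c + r * sphere)
                w_all.append(np.full(n_ang, wr * 4 * np.pi / n_ang))
                owner.append(np.full(n_ang, ic, dtype=np.int64))
        pts = np.vstack(pts_all)
        w = np.concatenate(w_all)
        if len(centers) > 1:
            w = w * _becke_weights(pts, centers, np.concatenate(owner))
        return Grid(
            pts,
            w,
            provenance={
                "kind": "atom_centered",
                "n_radial": n_rad,
                "n_angular": n_ang,
                "r_min": r_min,
                "r_max": r_max,
                "n_centers": len(centers),
            },
        )

    raise ValueError(f"unknown grid kind {kind!r}")


# ---------------------------------------------------------------------------
# model fields
# ---------------------------------------------------------------------------

@dataclass
class ModelField:
    """Closed-form scalar field with analytic gradient and known topology."""

    name: str
    dim: int
    value: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    topology: dict = dataclass_field(default_factory=dict)
    components: Callable[[np.ndarray], np.ndarray] | None = None  # vector models

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.value(np.atleast_2d(np.asarray(x, dtype=float)))


def _gaussian_mixture(centers, heights, widths, dim):
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    heights = np.asarray(heights, dtype=float)
    widths = np.asarray(widths, dtype=float)

    def value(x):
        x = np.atleast_2d(x)
        diff = x[:, None, :] - centers[None, :, :]
        r2 = np.einsum("nkd,nkd->nk", diff, diff)
        return (heights * np.exp(-r2 / widths**2)).sum(axis=1)

    def gradient(x):
        x = np.atleast_2d(x)
        diff = x[:, None, :] - centers[None, :, :]
        r2 = np.einsum("nkd,nkd->nk", diff, diff)
        coef = heights * np.exp(-r2 / widths**2) * (-2.0 / widths**2)
        return np.einsum("nk,nkd->nd", coef, diff)

    return value, gradient, centers, heights, widths


def make_field(model: str, **params) -> ModelField:
    """Build one of the closed-form model fields.

    two_gaussian
        f(x) = exp(-|x - a|^2) + exp(-|x - b|^2); params a, b.
    ring
        f(x) = -(|x| - radius)^2; default radius 1.
    gaussian_mixture
        sum_k h_k exp(-|x - c_k|^2 / w_k^2); params centers, heights, widths.
    promolecule
        sum_k N_k (alpha_k^3/pi) exp(-2 alpha_k |x - R_k|): superposed
        Slater-like atomic densities, each integrating to its population
        N_k; params centers, populations, exponents.
    shell_profile
        radial f(x) = sin(a r) exp(-b r); params a, b.
    ring_current
        model azimuthal current J = exp(-(rho^2 + z^2)/2) (-y, x, 0);
        value is |J| = rho exp(-(rho^2+z^2)/2), vanishing on the z axis.
    """
    if model == "two_gaussian":
        a = np.asarray(params["a"], dtype=float)
        b = np.asarray(params["b"], dtype=float)
        dim = len(a)
        value, gradient, *_ = _gaussian_mixture([a, b], [1.0, 1.0], [1.0, 1.0], dim)
        n_max = 1 if np.allclose(a, b) else 2
        return ModelField(
            "two_gaussian", dim, value, gradient,
            {"n_maxima": n_max, "maxima_positions": [a] if n_max == 1 else [a, b]},
        )

    if model == "ring":
        radius = float(params.get("radius", 1.0))
        dim = int(params.get("dim", 2))
        if radius <= 0:
            raise ValueError("ring radius must be positive")

        def value(x):
            r = np.linalg.norm(np.atleast_2d(x), axis=1)
            return -((r - radius) ** 2)

        def gradient(x):
            x = np.atleast_2d(x)
            r = np.linalg.norm(x, axis=1)
            safe = np.where(r > 0, r, 1.0)
            return (-2 * (r - radius) / safe)[:, None] * x

        return ModelField(
            "ring", dim, value, gradient,
            {"n_families": 1, "max_value": 0.0, "ring_radius": radius,
             "extended_maximum": True},
        )

    if model == "gaussian_mixture":
        centers = np.atleast_2d(np.asarray(params["centers"], dtype=float))
        k, dim = centers.shape
        heights = np.broadcast_to(np.asarray(params.get("heights", 1.0), dtype=float), (k,))
        widths = np.broadcast_to(np.asarray(params.get("widths", 1.0), dtype=float), (k,))
        if np.any(widths <= 0):
            raise ValueError("mixture widths must be positive")
        value, gradient, *_ = _gaussian_mixture(centers, heights, widths, dim)
        return ModelField(
            "gaussian_mixture", dim, value, gradient,
            {"n_maxima": k, "maxima_positions": list(centers)},
        )

    if model == "promolecule":
        centers = np.atleast_2d(np.asarray(params["centers"], dtype=float))
        pops = np.asarray(params["populations"], dtype=float)
        alphas = np.asarray(params["exponents"], dtype=float)
        if np.any(alphas <= 0) or np.any(pops < 0):
            raise ValueError("promolecule needs positive exponents and nonnegative populations")
        dim = centers.shape[1]
        pref = pops * alphas**3 / np.pi

        def value(x):
            x = np.atleast_2d(x)
            r = np.linalg.norm(x[:, None, :] - centers[None, :, :], axis=2)
            return (pref * np.exp(-2 * alphas * r)).sum(axis=1)

        def gradient(x):
            x = np.atleast_2d(x)
            diff = x[:, None, :] - centers[None, :, :]
            r = np.linalg.norm(diff, axis=2)
            safe = np.where(r > 0, r, 1.0)
            coef = pref * np.exp(-2 * alphas * r) * (-2 * alphas) / safe
            return np.einsum("nk,nkd->nd", coef, diff)

        return ModelField(
            "promolecule", dim, value, gradient,
            {"n_maxima": len(centers), "maxima_positions": list(centers),
             "analytic_total": float(pops.sum()),
             "analytic_populations": list(map(float, pops))},
        )

    if model == "shell_profile":
        a = float(params.get("a", np.pi))
        bb = float(params.get("b", 0.5))
        r_max = float(params.get("r_max", 6.0))

        def value(x):
            r = np.linalg.norm(np.atleast_2d(x), axis=1)
            return np.sin(a * r) * np.exp(-bb * r)

        def gradient(x):
            x = np.atleast_2d(x)
            r = np.linalg.norm(x, axis=1)
            safe = np.where(r > 0, r, 1.0)
            dfdr = (a * np.cos(a * r) - bb * np.sin(a * r)) * np.exp(-bb * r)
            return (dfdr / safe)[:, None] * x

        # lobe maxima of |sin(ar) e^{-br}| sit at r_k = (atan(a/b) + k pi)/a
        def n_lobes_within(R):
            return int(max(0, np.floor((a * R - np.arctan(a / bb)) / np.pi) + 1))

        return ModelField(
            "shell_profile", 3, value, gradient,
            {"n_abs_lobes_within": n_lobes_within,
             "lobe_radii": lambda k: (np.arctan(a / bb) + k * np.pi) / a,
             "n_abs_lobes_rmax": n_lobes_within(r_max)},
        )

    if model == "ring_current":
        def components(x):
            x = np.atleast_2d(x)
            amp = np.exp(-(x[:, 0] ** 2 + x[:, 1] ** 2 + x[:, 2] ** 2) / 2.0)
            return np.column_stack([-x[:, 1] * amp, x[:, 0] * amp, np.zeros(len(x))])

        def value(x):
            x = np.atleast_2d(x)
            rho = np.hypot(x[:, 0], x[:, 1])
            return rho * np.exp(-(rho**2 + x[:, 2] ** 2) / 2.0)

        def gradient(x):
            x = np.atleast_2d(x)
            rho = np.hypot(x[:, 0], x[:, 1])
            z = x[:, 2]
            amp = np.exp(-(rho**2 + z**2) / 2.0)
            safe = np.where(rho > 0, rho, 1.0)
            d_drho = amp * (1 - rho**2)
            g = np.empty_like(x)
            g[:, 0] = d_drho * x[:, 0] / safe
            g[:, 1] = d_drho * x[:, 1] / safe
            g[:, 2] = -rho * z * amp
            return g

        return ModelField(
            "ring_current", 3, value, gradient,
            {"zero_set": "z axis", "max_ring": {"rho": 1.0, "z": 0.0},
             "gradient_singular_on_axis": True},
            components=components,
        )

    raise ValueError(f"unknown model {model!r}")


def field_on_grid(model: ModelField, grid: Grid, name: str | None = None) -> ScalarField:
    """Evaluate a model on a grid as a ScalarField."""
    return ScalarField(model.value(grid.points), name=name or model.name, source="input")
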