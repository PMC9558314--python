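"""Electron density evaluation on arbitrary point sets.

rho(r) = sum_{mu nu} P_{mu nu} chi_mu(r) chi_nu(r), evaluated in chunks:
AO values are built per shell in cartesian form, mapped through the
basis's cartesian->spherical matrix, and contracted with the SCF density
matrix via BLAS.
"""

from __future__ import annotations

import numpy as np

from .integrals import CART_COMPS, ncart
from .scf import SCFResult

__all__ = ["ao_values", "density_on_points"]


def ao_values(basis, points: np.ndarray) -> np.ndarray:
    """(npoints, n_sph) matrix of AO values at the given points (bohr)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    npt = len(pts)
    cart = np.empty((npt, basis.n_cart))
    col = 0
    for l, center, exps, coefs in basis.shells:
        d = pts - center
        r2 = np.einsum("ij,ij->i", d, d)
        radial = np.zeros(npt)
        for a, c in zip(exps, coefs):
            radial += c * np.exp(-a * r2)
        for lx, ly, lz in CART_COMPS[l]:
            mono = np.ones(npt)
            if lx:
                mono = mono * d[:, 0] ** lx
            if ly:
                mono = mono * d[:, 1] ** ly
            if lz:
                mono = mono * d[:, 2] ** lz
            cart[:, col] = mono * radial
            col += 1
    return cart @ basis.cart2sph


def density_on_points(scf: SCFResult, points: np.ndarray, chunk: int = 50_000) -> np.ndarray:
    """Electron density rho(r) (e/bohr^3) at each point."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    out = np.empty(len(pts))
    P = scf.density
    for start in range(0, len(pts), chunk):
        X = ao_values(scf.basis, pts[start : start + chunk])
        out[start : start + chunk] = np.einsum("pi,pi->p", X @ P, X)
    return out
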