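"""Restricted Hartree-Fock for closed-shell molecules.

Conventional in-core RHF: full two-electron tensor, core-Hamiltonian
guess, DIIS acceleration, canonical orthogonalization.  The working AO
basis is spherical-harmonic (5d): cartesian integrals are transformed
with the real solid-harmonic combination matrix and AOs renormalized
from the overlap diagonal.  Intended for double-zeta, single-molecule
benchmark scale, not production use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .basis import ATOMIC_NUMBERS, CC_PVDZ, primitive_norm
from .integrals import build_shell_arrays, electron_repulsion, ncart, one_electron_matrices

__all__ = ["Molecule", "BasisInfo", "SCFResult", "build_basis", "rhf"]


@dataclass
class Molecule:
    """Nuclei only: (element symbol, xyz in bohr) plus total charge."""

    atoms: list  # [(symbol, (x, y, z)), ...]
    charge: int = 0

    @property
    def coords(self) -> np.ndarray:
        return np.array([a[1] for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS[a[0]] for a in self.atoms], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    def nuclear_repulsion(self) -> float:
        xyz = self.coords
        z = self.charges
        e = 0.0
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(xyz[i] - xyz[j])
        return e


# real solid harmonics for l=2 over cartesian monomials (xx, xy, xz, yy, yz, zz);
# rows span (2zz-xx-yy, xz, yz, xx-yy, xy); overall scale fixed by renormalization
_D_SPH = np.array(
    [
        [-1.0, 0.0, 0.0, -1.0, 0.0, 2.0],
        [0.0, 0.0, 1.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 1.0, 0.0],
        [1.0, 0.0, 0.0, -1.0, 0.0, 0.0],
        [0.0, 1.0, 0.0, 0.0, 0.0, 0.0],
    ]
)


@dataclass
class BasisInfo:
    shells: list  # (l, center, exps, normed coefs)
    arrays: tuple  # flattened shell arrays for the integral kernels
    cart2sph: np.ndarray  # (nbf_cart, nbf_sph), AO normalization folded in
    n_cart: int
    n_sph: int


def build_basis(mol: Molecule, basis_set=None) -> BasisInfo:
    basis_set = basis_set or CC_PVDZ
    shells = []
    for sym, xyz in mol.atoms:
        for l, exps, coefs in basis_set[sym]:
            normed = [c * primitive_norm(e, l) for e, c in zip(exps, coefs)]
            shells.append((l, np.asarray(xyz, dtype=float), np.asarray(exps, dtype=float),
                           np.asarray(normed)))
    arrays = build_shell_arrays(shells)
    blocks = []
    for l, *_ in shells:
        if l == 2:
            blocks.append(_D_SPH.T)  # (6, 5)
        else:
            blocks.append(np.eye(ncart(l)))
    n_cart = sum(b.shape[0] for b in blocks)
    n_sph = sum(b.shape[1] for b in blocks)
    cart2sph = np.zeros((n_cart, n_sph))
    i = j = 0
    for b in blocks:
        cart2sph[i : i + b.shape[0], j : j + b.shape[1]] = b
        i += b.shape[0]
        j += b.shape[1]
    return BasisInfo(shells, arrays, cart2sph, n_cart, n_sph)


@dataclass
class SCFResult:
    energy: float
    mo_coeff: np.ndarray  # (n_sph, n_mo)
    mo_energy: np.ndarray
    density: np.ndarray  # P = 2 C_occ C_occ^T (spherical AO basis)
    converged: bool
    n_iter: int
    basis: BasisInfo
    molecule: Molecule


def _transform_eri(eri_cart: np.ndarray, C: np.ndarray) -> np.ndarray:
    # one index per tensordot; the final axis reversal is a symmetry of the
    # tensor ((ij|kl) = (lk|ji)) and therefore harmless
    x = np.tensordot(eri_cart, C, axes=(3, 0))
    del eri_cart
    x = np.tensordot(x, C, axes=(2, 0))
    x = np.tensordot(x, C, axes=(1, 0))
    x = np.tensordot(x, C, axes=(0, 0))
    return np.ascontiguousarray(x)


def rhf(
    mol: Molecule,
    basis_set=None,
    conv_tol: float = 1e-9,
    max_iter: int = 120,
    verbose: bool = False,
) -> SCFResult:
    """Solve restricted Hartree-Fock; returns energy, MOs and AO density matrix."""
    if mol.n_electrons % 2:
        raise ValueError("RHF requires an even electron count")
    nocc = mol.n_electrons // 2
    info = build_basis(mol, basis_set)
    S_c, T_c, V_c = one_electron_matrices(*info.arrays, mol.charges, mol.coords)
    C0 = info.cart2sph
    S = C0.T @ S_c @ C0
    # renormalize AOs so diag(S) = 1, fold scaling into the cartesian->spherical map
    scale = 1.0 / np.sqrt(np.diag(S))
    C0 = C0 * scale
    info.cart2sph = C0
    S = C0.T @ S_c @ C0
    H = C0.T @ (T_c + V_c) @ C0
    eri = _transform_eri(electron_repulsion(*info.arrays), C0)

    evals, evecs = np.linalg.eigh(S)
    keep = evals > 1e-10 * evals.max()
    X = evecs[:, keep] / np.sqrt(evals[keep])

    e_nuc = mol.nuclear_repulsion()
    # core guess
    f_mo = X.T @ H @ X
    eps, cmo = np.linalg.eigh(f_mo)
    C = X @ cmo
    P = 2.0 * C[:, :nocc] @ C[:, :nocc].T

    diis_F, diis_err = [], []
    energy = 0.0
    converged = False
    for it in range(1, max_iter + 1):
        J = np.tensordot(eri, P, axes=([2, 3], [0, 1]))
        K = np.tensordot(eri, P, axes=([1, 2], [1, 0]))
        F = H + J - 0.5 * K
        e_new = 0.5 * np.sum(P * (H + F)) + e_nuc
        err = F @ P @ S - S @ P @ F
        diis_F.append(F.copy())
        diis_err.append(err.ravel())
        if len(diis_F) > 8:
            diis_F.pop(0)
            diis_err.pop(0)
        if len(diis_F) > 1:
            m = len(diis_F)
            B = -np.ones((m + 1, m + 1))
            B[m, m] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = diis_err[i] @ diis_err[j]
            rhs = np.zeros(m + 1)
            rhs[m] = -1.0
            try:
                coef = np.linalg.solve(B, rhs)[:m]
                F = sum(c * Fi for c, Fi in zip(coef, diis_F))
            except np.linalg.LinAlgError:
                pass
        f_mo = X.T @ F @ X
        eps, cmo = np.linalg.eigh(f_mo)
        C = X @ cmo
        P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        de = abs(e_new - energy)
        err_norm = np.abs(err).max()
        energy = e_new
        if verbose:
            print(f"iter {it:3d}  E = {energy:.10f}  dE = {de:.2e}  |err| = {err_norm:.2e}")
        if de < conv_tol and err_norm < 1e-6:
            converged = True
            break
    return SCFResult(
        energy=float(energy),
        mo_coeff=C,
        mo_energy=eps,
        density=P,
        converged=converged,
        n_iter=it,
        basis=info,
        molecule=mol,
    )
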