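"""Molecular integrals over contracted cartesian Gaussians.

McMurchie-Davidson scheme: cartesian Gaussian products are expanded in
Hermite Gaussians (E coefficients), Coulomb integrals reduce to Hermite
Coulomb integrals R built on the Boys function.  Supports s, p and d
shells (all that cc-pVDZ needs for H-Ne).  The two-electron integrals
are assembled shell-quartet-wise with 8-fold permutational symmetry and
Schwarz screening into a full 4-index array (fine at double-zeta,
single-molecule scale).

Cartesian component order per shell: lexicographic with decreasing lx
(l=1: x, y, z;  l=2: xx, xy, xz, yy, yz, zz).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["build_shell_arrays", "one_electron", "electron_repulsion", "CART_COMPS"]

# cartesian components per l, concatenated; offsets per l
CART_COMPS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
    2: [(2, 0, 0), (1, 1, 0), (1, 0, 1), (0, 2, 0), (0, 1, 1), (0, 0, 2)],
}
_COMP_FLAT = np.array(
    [c for l in range(3) for c in CART_COMPS[l]], dtype=np.int64
)
_COMP_OFF = np.array([0, 1, 4, 10], dtype=np.int64)


def ncart(l: int) -> int:
    return (l + 1) * (l + 2) // 2


def build_shell_arrays(shells):
    """Flatten a list of (l, center, exps, coefs) into numba-friendly arrays.

    Primitive coefficients arrive already multiplied by primitive norms.
    Returns (sh_l, sh_center, sh_pstart, prim_exp, prim_coef, ao_start).
    """
    sh_l = np.array([s[0] for s in shells], dtype=np.int64)
    sh_center = np.array([s[1] for s in shells], dtype=float)
    counts = [len(s[2]) for s in shells]
    sh_pstart = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    prim_exp = np.concatenate([s[2] for s in shells]).astype(float)
    prim_coef = np.concatenate([s[3] for s in shells]).astype(float)
    ao_start = np.concatenate([[0], np.cumsum([ncart(l) for l in sh_l])]).astype(np.int64)
    return sh_l, sh_center, sh_pstart, prim_exp, prim_coef, ao_start


@njit(cache=True)
def _boys(mmax, T, F):
    if T < 1e-13:
        for m in range(mmax + 1):
            F[m] = 1.0 / (2 * m + 1)
        return
    if T < 35.0:
        expT = np.exp(-T)
        term = 1.0 / (2 * mmax + 1)
        s = term
        k = 1
        while True:
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            s += term
            if term < 1e-17 * s:
                break
            k += 1
        F[mmax] = expT * s
        for m in range(mmax, 0, -1):
            F[m - 1] = (2.0 * T * F[m] + expT) / (2 * m - 1)
    else:
        expT = np.exp(-T)
        F[0] = 0.5 * np.sqrt(np.pi / T)
        for m in range(mmax):
            F[m + 1] = ((2 * m + 1) * F[m] - expT) / (2.0 * T)


@njit(cache=True)
def _fill_E(la, lb, a, b, AB, E):
    """Hermite expansion coefficients E[i, j, t] for one cartesian direction.

    AB = A - B.  E has shape (la+1, lb+1, la+lb+1) at least.
    """
    p = a + b
    E[:, :, :] = 0.0
    E[0, 0, 0] = np.exp(-a * b / p * AB * AB)
    xpa = -b / p * AB
    xpb = a / p * AB
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                for t in range(i + j + 1):
                    val = xpa * E[i - 1, 0, t]
                    if t > 0:
                        val += E[i - 1, 0, t - 1] / (2 * p)
                    if t + 1 <= i + j:
                        val += (t + 1) * E[i - 1, 0, t + 1]
                    E[i, 0, t] = val
            else:
                for t in range(i + j + 1):
                    val = xpb * E[i, j - 1, t]
                    if t > 0:
                        val += E[i, j - 1, t - 1] / (2 * p)
                    if t + 1 <= i + j:
                        val += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = val


@njit(cache=True)
def _fill_R(L, alpha, X, Y, Z, R4, F):
    """Hermite Coulomb integrals R4[n, t, u, v] up to t+u+v <= L.

    Only entries with t+u+v <= L - n are written, and the consumers read
    only those, so R4 is deliberately not cleared between calls.
    """
    T = alpha * (X * X + Y * Y + Z * Z)
    _boys(L, T, F)
    sign = 1.0
    for n in range(L + 1):
        R4[n, 0, 0, 0] = sign * F[n]
        sign *= -2.0 * alpha
    for total in range(1, L + 1):
        for n in range(L - total + 1):
            for t in range(total + 1):
                for u in range(total - t + 1):
                    v = total - t - u
                    if t > 0:
                        val = X * R4[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * R4[n + 1, t - 2, u, v]
                        R4[n, t, u, v] = val
                    elif u > 0:
                        val = Y * R4[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * R4[n + 1, t, u - 2, v]
                        R4[n, t, u, v] = val
                    else:
                        val = Z * R4[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * R4[n + 1, t, u, v - 2]
                        R4[n, t, u, v] = val


@njit(cache=True)
def one_electron(sh_l, sh_center, sh_pstart, prim_exp, prim_coef, ao_start,
                 comp_flat, comp_off, charges, coords):
    """Overlap, kinetic, and nuclear-attraction matrices (cartesian AO basis)."""
    nsh = len(sh_l)
    nbf = ao_start[nsh]
    S = np.zeros((nbf, nbf))
    Tm = np.zeros((nbf, nbf))
    V = np.zeros((nbf, nbf))
    nat = len(charges)
    for A in range(nsh):
        la = sh_l[A]
        for B in range(A + 1):
            lb = sh_l[B]
            L = la + lb
            Ex = np.zeros((la + 1, lb + 3, L + 3))
            Ey = np.zeros((la + 1, lb + 3, L + 3))
            Ez = np.zeros((la + 1, lb + 3, L + 3))
            Rt = np.zeros((L + 1, L + 1, L + 1, L + 1))
            Fb = np.empty(L + 1)
            ncA = (la + 1) * (la + 2) // 2
            ncB = (lb + 1) * (lb + 2) // 2
            block_S = np.zeros((ncA, ncB))
            block_T = np.zeros((ncA, ncB))
            block_V = np.zeros((ncA, ncB))
            for ip in range(sh_pstart[A], sh_pstart[A + 1]):
                a = prim_exp[ip]
                for jp in range(sh_pstart[B], sh_pstart[B + 1]):
                    b = prim_exp[jp]
                    cc = prim_coef[ip] * prim_coef[jp]
                    p = a + b
                    ABx = sh_center[A, 0] - sh_center[B, 0]
                    ABy = sh_center[A, 1] - sh_center[B, 1]
                    ABz = sh_center[A, 2] - sh_center[B, 2]
                    if a * b / p * (ABx * ABx + ABy * ABy + ABz * ABz) > 46.0:
                        continue  # exp(-46) ~ 1e-20
                    _fill_E(la, lb + 2, a, b, ABx, Ex)
                    _fill_E(la, lb + 2, a, b, ABy, Ey)
                    _fill_E(la, lb + 2, a, b, ABz, Ez)
                    Px = (a * sh_center[A, 0] + b * sh_center[B, 0]) / p
                    Py = (a * sh_center[A, 1] + b * sh_center[B, 1]) / p
                    Pz = (a * sh_center[A, 2] + b * sh_center[B, 2]) / p
                    fac = (np.pi / p) ** 1.5
                    for ca in range(ncA):
                        ax = comp_flat[comp_off[la] + ca, 0]
                        ay = comp_flat[comp_off[la] + ca, 1]
                        az = comp_flat[comp_off[la] + ca, 2]
                        for cb in range(ncB):
                            bx = comp_flat[comp_off[lb] + cb, 0]
                            by = comp_flat[comp_off[lb] + cb, 1]
                            bz = comp_flat[comp_off[lb] + cb, 2]
                            sx = Ex[ax, bx, 0]
                            sy = Ey[ay, by, 0]
                            sz = Ez[az, bz, 0]
                            # 1D kinetic pieces
                            tx = -2.0 * b * b * Ex[ax, bx + 2, 0] + b * (2 * bx + 1) * sx
                            if bx >= 2:
                                tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                            ty = -2.0 * b * b * Ey[ay, by + 2, 0] + b * (2 * by + 1) * sy
                            if by >= 2:
                                ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                            tz = -2.0 * b * b * Ez[az, bz + 2, 0] + b * (2 * bz + 1) * sz
                            if bz >= 2:
                                tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                            block_S[ca, cb] += cc * fac * sx * sy * sz
                            block_T[ca, cb] += cc * fac * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
                            # nuclear attraction
                            vsum = 0.0
                            for iat in range(nat):
                                _fill_R(L, p, Px - coords[iat, 0], Py - coords[iat, 1],
                                        Pz - coords[iat, 2], Rt, Fb)
                                acc = 0.0
                                for t in range(ax + bx + 1):
                                    for u in range(ay + by + 1):
                                        for v in range(az + bz + 1):
                                            acc += (Ex[ax, bx, t] * Ey[ay, by, u]
                                                    * Ez[az, bz, v] * Rt[0, t, u, v])
                                vsum -= charges[iat] * acc
                            block_V[ca, cb] += cc * 2.0 * np.pi / p * vsum
            i0 = ao_start[A]
            j0 = ao_start[B]
            for ca in range(ncA):
                for cb in range(ncB):
                    S[i0 + ca, j0 + cb] = block_S[ca, cb]
                    S[j0 + cb, i0 + ca] = block_S[ca, cb]
                    Tm[i0 + ca, j0 + cb] = block_T[ca, cb]
                    Tm[j0 + cb, i0 + ca] = block_T[ca, cb]
                    V[i0 + ca, j0 + cb] = block_V[ca, cb]
                    V[j0 + cb, i0 + ca] = block_V[ca, cb]
    return S, Tm, V


@njit(cache=True)
def _pair_data(sh_l, sh_center, sh_pstart, prim_exp, prim_coef, comp_flat, comp_off):
    """Precompute, per shell pair (A >= B), surviving primitive-pair Hermite data.

    For every primitive pair the full E3 coefficient cube
    E3[compA, compB, t, u, v] (c_i c_j folded in) is stored flattened.
    """
    nsh = len(sh_l)
    # enumerate pairs
    npair = nsh * (nsh + 1) // 2
    pair_A = np.empty(npair, dtype=np.int64)
    pair_B = np.empty(npair, dtype=np.int64)
    k = 0
    for A in range(nsh):
        for B in range(A + 1):
            pair_A[k] = A
            pair_B[k] = B
            k += 1
    # first pass: count surviving prim pairs and data size
    pp_count = np.zeros(npair, dtype=np.int64)
    data_size = np.zeros(npair, dtype=np.int64)
    for ip in range(npair):
        A, B = pair_A[ip], pair_B[ip]
        la, lb = sh_l[A], sh_l[B]
        L = la + lb
        ncA = (la + 1) * (la + 2) // 2
        ncB = (lb + 1) * (lb + 2) // 2
        ABx = sh_center[A, 0] - sh_center[B, 0]
        ABy = sh_center[A, 1] - sh_center[B, 1]
        ABz = sh_center[A, 2] - sh_center[B, 2]
        r2 = ABx * ABx + ABy * ABy + ABz * ABz
        cnt = 0
        for i in range(sh_pstart[A], sh_pstart[A + 1]):
            for j in range(sh_pstart[B], sh_pstart[B + 1]):
                a, b = prim_exp[i], prim_exp[j]
                if a * b / (a + b) * r2 <= 46.0:
                    cnt += 1
        pp_count[ip] = cnt
        data_size[ip] = cnt * ncA * ncB * (L + 1) ** 3
    pp_off = np.zeros(npair + 1, dtype=np.int64)
    data_off = np.zeros(npair + 1, dtype=np.int64)
    for ip in range(npair):
        pp_off[ip + 1] = pp_off[ip] + pp_count[ip]
        data_off[ip + 1] = data_off[ip] + data_size[ip]
    ntot = pp_off[npair]
    pp_p = np.empty(ntot)
    pp_P = np.empty((ntot, 3))
    E3 = np.empty(data_off[npair])
    # second pass: fill
    for ip in range(npair):
        A, B = pair_A[ip], pair_B[ip]
        la, lb = sh_l[A], sh_l[B]
        L = la + lb
        ncA = (la + 1) * (la + 2) // 2
        ncB = (lb + 1) * (lb + 2) // 2
        nL = L + 1
        ABx = sh_center[A, 0] - sh_center[B, 0]
        ABy = sh_center[A, 1] - sh_center[B, 1]
        ABz = sh_center[A, 2] - sh_center[B, 2]
        r2 = ABx * ABx + ABy * ABy + ABz * ABz
        Ex = np.zeros((la + 1, lb + 1, L + 1))
        Ey = np.zeros((la + 1, lb + 1, L + 1))
        Ez = np.zeros((la + 1, lb + 1, L + 1))
        idx = pp_off[ip]
        dpos = data_off[ip]
        for i in range(sh_pstart[A], sh_pstart[A + 1]):
            for j in range(sh_pstart[B], sh_pstart[B + 1]):
                a, b = prim_exp[i], prim_exp[j]
                p = a + b
                if a * b / p * r2 > 46.0:
                    continue
                cc = prim_coef[i] * prim_coef[j]
                _fill_E(la, lb, a, b, ABx, Ex)
                _fill_E(la, lb, a, b, ABy, Ey)
                _fill_E(la, lb, a, b, ABz, Ez)
                pp_p[idx] = p
                pp_P[idx, 0] = (a * sh_center[A, 0] + b * sh_center[B, 0]) / p
                pp_P[idx, 1] = (a * sh_center[A, 1] + b * sh_center[B, 1]) / p
                pp_P[idx, 2] = (a * sh_center[A, 2] + b * sh_center[B, 2]) / p
                for ca in range(ncA):
                    ax = comp_flat[comp_off[la] + ca, 0]
                    ay = comp_flat[comp_off[la] + ca, 1]
                    az = comp_flat[comp_off[la] + ca, 2]
                    for cb in range(ncB):
                        bx = comp_flat[comp_off[lb] + cb, 0]
                        by = comp_flat[comp_off[lb] + cb, 1]
                        bz = comp_flat[comp_off[lb] + cb, 2]
                        base = dpos + ((ca * ncB + cb) * nL * nL * nL)
                        for t in range(nL):
                            for u in range(nL):
                                for v in range(nL):
                                    val = 0.0
                                    if t <= ax + bx and u <= ay + by and v <= az + bz:
                                        val = cc * Ex[ax, bx, t] * Ey[ay, by, u] * Ez[az, bz, v]
                                    E3[base + (t * nL + u) * nL + v] = val
                idx += 1
                dpos += ncA * ncB * nL * nL * nL
    return pair_A, pair_B, pp_off, data_off, pp_p, pp_P, E3


@njit(cache=True)
def _eri_kernel(sh_l, ao_start, comp_flat, comp_off,
                pair_A, pair_B, pp_off, data_off, pp_p, pp_P, E3, eri, schwarz):
    npair = len(pair_A)
    nmax = 0
    for ip in range(npair):
        L = sh_l[pair_A[ip]] + sh_l[pair_B[ip]]
        if L > nmax:
            nmax = L
    Lbig = 2 * nmax
    R4 = np.zeros((Lbig + 1, Lbig + 1, Lbig + 1, Lbig + 1))
    Fb = np.empty(Lbig + 1)
    for ijp in range(npair):
        A, B = pair_A[ijp], pair_B[ijp]
        la, lb = sh_l[A], sh_l[B]
        Lab = la + lb
        nLab = Lab + 1
        ncA = (la + 1) * (la + 2) // 2
        ncB = (lb + 1) * (lb + 2) // 2
        for klp in range(ijp + 1):
            if schwarz[ijp] * schwarz[klp] < 1e-13:
                continue
            C, D = pair_A[klp], pair_B[klp]
            lc, ld = sh_l[C], sh_l[D]
            Lcd = lc + ld
            nLcd = Lcd + 1
            ncC = (lc + 1) * (lc + 2) // 2
            ncD = (ld + 1) * (ld + 2) // 2
            L = Lab + Lcd
            block = np.zeros((ncA, ncB, ncC, ncD))
            for ii in range(pp_off[ijp], pp_off[ijp + 1]):
                p = pp_p[ii]
                bbase = data_off[ijp] + (ii - pp_off[ijp]) * ncA * ncB * nLab ** 3
                for jj in range(pp_off[klp], pp_off[klp + 1]):
                    q = pp_p[jj]
                    alpha = p * q / (p + q)
                    fac = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                    _fill_R(L, alpha,
                            pp_P[ii, 0] - pp_P[jj, 0],
                            pp_P[ii, 1] - pp_P[jj, 1],
                            pp_P[ii, 2] - pp_P[jj, 2], R4, Fb)
                    kbase = data_off[klp] + (jj - pp_off[klp]) * ncC * ncD * nLcd ** 3
                    for ca in range(ncA):
                        ax = comp_flat[comp_off[la] + ca, 0]
                        ay = comp_flat[comp_off[la] + ca, 1]
                        az = comp_flat[comp_off[la] + ca, 2]
                        for cb in range(ncB):
                            bx = comp_flat[comp_off[lb] + cb, 0]
                            by = comp_flat[comp_off[lb] + cb, 1]
                            bz = comp_flat[comp_off[lb] + cb, 2]
                            tmax = ax + bx
                            umax = ay + by
                            vmax = az + bz
                            boff = bbase + (ca * ncB + cb) * nLab ** 3
                            for cc_ in range(ncC):
                                cx = comp_flat[comp_off[lc] + cc_, 0]
                                cy = comp_flat[comp_off[lc] + cc_, 1]
                                cz = comp_flat[comp_off[lc] + cc_, 2]
                                for cd in range(ncD):
                                    dx = comp_flat[comp_off[ld] + cd, 0]
                                    dy = comp_flat[comp_off[ld] + cd, 1]
                                    dz = comp_flat[comp_off[ld] + cd, 2]
                                    t2max = cx + dx
                                    u2max = cy + dy
                                    v2max = cz + dz
                                    koff = kbase + (cc_ * ncD + cd) * nLcd ** 3
                                    acc = 0.0
                                    for t in range(tmax + 1):
                                        for u in range(umax + 1):
                                            for v in range(vmax + 1):
                                                e1 = E3[boff + (t * nLab + u) * nLab + v]
                                                if e1 == 0.0:
                                                    continue
                                                for t2 in range(t2max + 1):
                                                    for u2 in range(u2max + 1):
                                                        s2 = 0.0
                                                        for v2 in range(v2max + 1):
                                                            e2 = E3[koff + (t2 * nLcd + u2) * nLcd + v2]
                                                            if ((v2 & 1) == 1):
                                                                e2 = -e2
                                                            s2 += e2 * R4[0, t + t2, u + u2, v + v2]
                                                        if (((t2 + u2) & 1) == 1):
                                                            s2 = -s2
                                                        acc += e1 * s2
                                    block[ca, cb, cc_, cd] += fac * acc
            # scatter with 8-fold symmetry
            i0, j0, k0, l0 = ao_start[A], ao_start[B], ao_start[C], ao_start[D]
            for ca in range(ncA):
                for cb in range(ncB):
                    for cc_ in range(ncC):
                        for cd in range(ncD):
                            val = block[ca, cb, cc_, cd]
                            i, j, k, l = i0 + ca, j0 + cb, k0 + cc_, l0 + cd
                            eri[i, j, k, l] = val
                            eri[j, i, k, l] = val
                            eri[i, j, l, k] = val
                            eri[j, i, l, k] = val
                            eri[k, l, i, j] = val
                            eri[l, k, i, j] = val
                            eri[k, l, j, i] = val
                            eri[l, k, j, i] = val


@njit(cache=True)
def _schwarz_diag(sh_l, comp_flat, comp_off, pair_A, pair_B, pp_off, data_off, pp_p, pp_P, E3):
    """sqrt(max |(ab|ab)|) per shell pair, for quartet screening."""
    npair = len(pair_A)
    out = np.empty(npair)
    nmax = 0
    for ip in range(npair):
        L = sh_l[pair_A[ip]] + sh_l[pair_B[ip]]
        if L > nmax:
            nmax = L
    R4 = np.zeros((2 * nmax + 1, 2 * nmax + 1, 2 * nmax + 1, 2 * nmax + 1))
    Fb = np.empty(2 * nmax + 1)
    for ijp in range(npair):
        A, B = pair_A[ijp], pair_B[ijp]
        la, lb = sh_l[A], sh_l[B]
        Lab = la + lb
        nLab = Lab + 1
        ncA = (la + 1) * (la + 2) // 2
        ncB = (lb + 1) * (lb + 2) // 2
        best = 0.0
        for ca in range(ncA):
            ax = comp_flat[comp_off[la] + ca, 0]
            ay = comp_flat[comp_off[la] + ca, 1]
            az = comp_flat[comp_off[la] + ca, 2]
            for cb in range(ncB):
                bx = comp_flat[comp_off[lb] + cb, 0]
                by = comp_flat[comp_off[lb] + cb, 1]
                bz = comp_flat[comp_off[lb] + cb, 2]
                acc = 0.0
                for ii in range(pp_off[ijp], pp_off[ijp + 1]):
                    p = pp_p[ii]
                    boff = (data_off[ijp] + (ii - pp_off[ijp]) * ncA * ncB * nLab ** 3
                            + (ca * ncB + cb) * nLab ** 3)
                    for jj in range(pp_off[ijp], pp_off[ijp + 1]):
                        q = pp_p[jj]
                        alpha = p * q / (p + q)
                        fac = 2.0 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
                        _fill_R(2 * Lab, alpha,
                                pp_P[ii, 0] - pp_P[jj, 0],
                                pp_P[ii, 1] - pp_P[jj, 1],
                                pp_P[ii, 2] - pp_P[jj, 2], R4, Fb)
                        koff = (data_off[ijp] + (jj - pp_off[ijp]) * ncA * ncB * nLab ** 3
                                + (ca * ncB + cb) * nLab ** 3)
                        for t in range(ax + bx + 1):
                            for u in range(ay + by + 1):
                                for v in range(az + bz + 1):
                                    e1 = E3[boff + (t * nLab + u) * nLab + v]
                                    if e1 == 0.0:
                                        continue
                                    for t2 in range(ax + bx + 1):
                                        for u2 in range(ay + by + 1):
                                            for v2 in range(az + bz + 1):
                                                e2 = E3[koff + (t2 * nLab + u2) * nLab + v2]
                                                if (((t2 + u2 + v2) & 1) == 1):
                                                    e2 = -e2
                                                acc += fac * e1 * e2 * R4[0, t + t2, u + u2, v + v2]
                    if abs(acc) > best:
                        best = abs(acc)
        out[ijp] = np.sqrt(best)
    return out


def electron_repulsion(sh_l, sh_center, sh_pstart, prim_exp, prim_coef, ao_start):
    """Full (cartesian) two-electron integral tensor (chemist's notation)."""
    nbf = int(ao_start[len(sh_l)])
    pair = _pair_data(sh_l, sh_center, sh_pstart, prim_exp, prim_coef,
                      _COMP_FLAT, _COMP_OFF)
    schwarz = _schwarz_diag(sh_l, _COMP_FLAT, _COMP_OFF, *pair)
    eri = np.zeros((nbf, nbf, nbf, nbf))
    _eri_kernel(sh_l, ao_start, _COMP_FLAT, _COMP_OFF, *pair, eri, schwarz)
    return eri


def one_electron_matrices(sh_l, sh_center, sh_pstart, prim_exp, prim_coef, ao_start,
                          charges, coords):
    return one_electron(sh_l, sh_center, sh_pstart, prim_exp, prim_coef, ao_start,
                        _COMP_FLAT, _COMP_OFF,
                        np.asarray(charges, dtype=float), np.asarray(coords, dtype=float))
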