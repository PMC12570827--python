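"""Gaussian integral kernels (McMurchie–Davidson scheme), numba-jitted.

All kernels work on the flattened Cartesian-AO arrays produced by
:func:`headtail.qchem.basis.build_basis`.  Two-electron integrals are
returned as a symmetric compound-index matrix ``eri[ij, kl]`` with
``ij = i*(i+1)/2 + j`` for ``i >= j``, with Schwarz screening applied.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["overlap_kinetic", "nuclear_attraction", "eri_compound", "build_jk"]

_MAXL = 2          # highest cartesian angular momentum per AO (s, p, d)
_TDIM = 2 * _MAXL + 1


@njit(cache=True)
def _boys(L, T, F):
    """Fill F[0..L] with Boys functions F_m(T)."""
    if T < 1e-13:
        for m in range(L + 1):
            F[m] = 1.0 / (2.0 * m + 1.0)
        return
    if T < 35.0:
        # series for F_L, then stable downward recursion
        term = 1.0 / (2.0 * L + 1.0)
        s = term
        k = 1
        while k < 300:
            term *= 2.0 * T / (2.0 * L + 2.0 * k + 1.0)
            s += term
            if term < 1e-17 * s:
                break
            k += 1
        eT = math.exp(-T)
        F[L] = eT * s
        for m in range(L - 1, -1, -1):
            F[m] = (2.0 * T * F[m + 1] + eT) / (2.0 * m + 1.0)
    else:
        F[0] = 0.5 * math.sqrt(math.pi / T) * math.erf(math.sqrt(T))
        eT = math.exp(-T)
        for m in range(1, L + 1):
            F[m] = ((2.0 * m - 1.0) * F[m - 1] - eT) / (2.0 * T)


@njit(cache=True)
def _e_table(l1, l2, a, b, AB, E):
    """Hermite expansion coefficients E[i, j, t] for a 1D Gaussian pair.

    AB = A - B.  E includes the exponential prefactor exp(-mu*AB^2).
    """
    p = a + b
    mu = a * b / p
    one_over_2p = 0.5 / p
    PA = -b * AB / p
    PB = a * AB / p
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            for t in range(l1 + l2 + 2):
                E[i, j, t] = 0.0
    E[0, 0, 0] = math.exp(-mu * AB * AB)
    for i in range(1, l1 + 1):
        for t in range(i + 1):
            v = PA * E[i - 1, 0, t] + (t + 1) * E[i - 1, 0, t + 1]
            if t > 0:
                v += one_over_2p * E[i - 1, 0, t - 1]
            E[i, 0, t] = v
    for j in range(1, l2 + 1):
        for i in range(l1 + 1):
            for t in range(i + j + 1):
                v = PB * E[i, j - 1, t] + (t + 1) * E[i, j - 1, t + 1]
                if t > 0:
                    v += one_over_2p * E[i, j - 1, t - 1]
                E[i, j, t] = v


@njit(cache=True)
def _r_table(tx, ty, tz, minus_two_theta, X, Y, Z, F, Rm):
    """Hermite Coulomb integrals R_{t,u,v} (m=0 slice of Rm) via recursion."""
    L = tx + ty + tz
    pw = 1.0
    for m in range(L + 1):
        Rm[m, 0, 0, 0] = pw * F[m]
        pw *= minus_two_theta
    for t in range(1, tx + 1):
        for m in range(L - t + 1):
            v = X * Rm[m + 1, t - 1, 0, 0]
            if t > 1:
                v += (t - 1) * Rm[m + 1, t - 2, 0, 0]
            Rm[m, t, 0, 0] = v
    for u in range(1, ty + 1):
        for t in range(tx + 1):
            for m in range(L - t - u + 1):
                v = Y * Rm[m + 1, t, u - 1, 0]
                if u > 1:
                    v += (u - 1) * Rm[m + 1, t, u - 2, 0]
                Rm[m, t, u, 0] = v
    for w in range(1, tz + 1):
        for u in range(ty + 1):
            for t in range(tx + 1):
                for m in range(L - t - u - w + 1):
                    v = Z * Rm[m + 1, t, u, w - 1]
                    if w > 1:
                        v += (w - 1) * Rm[m + 1, t, u, w - 2]
                    Rm[m, t, u, w] = v


@njit(cache=True)
def overlap_kinetic(powers, centers, prim_start, prim_count, pexp, pcoef):
    """Overlap and kinetic-energy matrices."""
    nao = powers.shape[0]
    S = np.zeros((nao, nao))
    T = np.zeros((nao, nao))
    lmax = _MAXL
    E = np.empty((lmax + 1, lmax + 3, 2 * lmax + 4))
    Sx = np.empty(3)          # 1D overlaps at (li, lj)
    for i in range(nao):
        for j in range(i + 1):
            s_ij = 0.0
            t_ij = 0.0
            for ip in range(prim_start[i], prim_start[i] + prim_count[i]):
                a = pexp[ip]
                ca = pcoef[ip]
                for jp in range(prim_start[j], prim_start[j] + prim_count[j]):
                    b = pexp[jp]
                    cb = pcoef[jp]
                    p = a + b
                    sq = math.sqrt(math.pi / p)
                    # per-dimension overlaps incl. lj+2 / lj-2 shifts for kinetic
                    t_term = 0.0
                    s_term = 1.0
                    # first pass: plain overlaps per dim
                    for d in range(3):
                        l1 = powers[i, d]
                        l2 = powers[j, d]
                        AB = centers[i, d] - centers[j, d]
                        _e_table(l1, l2 + 2, a, b, AB, E)
                        s0 = E[l1, l2, 0] * sq
                        Sx[d] = s0
                        s_term *= s0
                    # kinetic: sum over dims of 1D kinetic x other overlaps
                    for d in range(3):
                        l1 = powers[i, d]
                        l2 = powers[j, d]
                        AB = centers[i, d] - centers[j, d]
                        _e_table(l1, l2 + 2, a, b, AB, E)
                        k1d = -2.0 * b * b * E[l1, l2 + 2, 0] * sq
                        k1d += b * (2.0 * l2 + 1.0) * E[l1, l2, 0] * sq
                        if l2 >= 2:
                            k1d -= 0.5 * l2 * (l2 - 1.0) * E[l1, l2 - 2, 0] * sq
                        other = 1.0
                        for dd in range(3):
                            if dd != d:
                                other *= Sx[dd]
                        t_term += k1d * other
                    s_ij += ca * cb * s_term
                    t_ij += ca * cb * t_term
            S[i, j] = s_ij
            S[j, i] = s_ij
            T[i, j] = t_ij
            T[j, i] = t_ij
    return S, T


@njit(cache=True)
def nuclear_attraction(powers, centers, prim_start, prim_count, pexp, pcoef,
                       atom_charges, atom_coords):
    """Nuclear-attraction matrix (negative-definite for bound systems)."""
    nao = powers.shape[0]
    natom = atom_charges.shape[0]
    V = np.zeros((nao, nao))
    lmax = _MAXL
    Ex = np.empty((lmax + 1, lmax + 1, 2 * lmax + 2))
    Ey = np.empty((lmax + 1, lmax + 1, 2 * lmax + 2))
    Ez = np.empty((lmax + 1, lmax + 1, 2 * lmax + 2))
    L_all = 6 * lmax
    F = np.empty(L_all + 1)
    Rm = np.empty((L_all + 1, 2 * lmax + 1, 2 * lmax + 1, 2 * lmax + 1))
    for i in range(nao):
        for j in range(i + 1):
            lx1, ly1, lz1 = powers[i, 0], powers[i, 1], powers[i, 2]
            lx2, ly2, lz2 = powers[j, 0], powers[j, 1], powers[j, 2]
            tx = lx1 + lx2
            ty = ly1 + ly2
            tz = lz1 + lz2
            L = tx + ty + tz
            v_ij = 0.0
            for ip in range(prim_start[i], prim_start[i] + prim_count[i]):
                a = pexp[ip]
                ca = pcoef[ip]
                for jp in range(prim_start[j], prim_start[j] + prim_count[j]):
                    b = pexp[jp]
                    cb = pcoef[jp]
                    p = a + b
                    Px = (a * centers[i, 0] + b * centers[j, 0]) / p
                    Py = (a * centers[i, 1] + b * centers[j, 1]) / p
                    Pz = (a * centers[i, 2] + b * centers[j, 2]) / p
                    _e_table(lx1, lx2, a, b, centers[i, 0] - centers[j, 0], Ex)
                    _e_table(ly1, ly2, a, b, centers[i, 1] - centers[j, 1], Ey)
                    _e_table(lz1, lz2, a, b, centers[i, 2] - centers[j, 2], Ez)
                    pref = 2.0 * math.pi / p * ca * cb
                    for ic in range(natom):
                        X = Px - atom_coords[ic, 0]
                        Y = Py - atom_coords[ic, 1]
                        Z = Pz - atom_coords[ic, 2]
                        T2 = p * (X * X + Y * Y + Z * Z)
                        _boys(L, T2, F)
                        _r_table(tx, ty, tz, -2.0 * p, X, Y, Z, F, Rm)
                        s = 0.0
                        for t in range(tx + 1):
                            ex = Ex[lx1, lx2, t]
                            for u in range(ty + 1):
                                exy = ex * Ey[ly1, ly2, u]
                                for w in range(tz + 1):
                                    s += exy * Ez[lz1, lz2, w] * Rm[0, t, u, w]
                        v_ij -= pref * atom_charges[ic] * s
            V[i, j] = v_ij
            V[j, i] = v_ij
    return V


@njit(cache=True)
def _pair_data(powers, centers, prim_start, prim_count, pexp, pcoef):
    """Precompute exponents, centers-of-charge and Hermite coefficients for
    every unique AO pair and primitive pair."""
    nao = powers.shape[0]
    npair = nao * (nao + 1) // 2
    maxpp = 0
    for i in range(nao):
        if prim_count[i] > maxpp:
            maxpp = prim_count[i]
    maxpp = maxpp * maxpp
    pp_n = np.zeros(npair, dtype=np.int64)
    pp_p = np.zeros((npair, maxpp))
    pp_P = np.zeros((npair, maxpp, 3))
    pp_E = np.zeros((npair, maxpp, 3, _TDIM))
    pp_t = np.zeros((npair, 3), dtype=np.int64)
    E = np.empty((_MAXL + 1, _MAXL + 1, 2 * _MAXL + 2))
    for i in range(nao):
        for j in range(i + 1):
            ij = i * (i + 1) // 2 + j
            for d in range(3):
                pp_t[ij, d] = powers[i, d] + powers[j, d]
            n = 0
            for ip in range(prim_start[i], prim_start[i] + prim_count[i]):
                a = pexp[ip]
                ca = pcoef[ip]
                for jp in range(prim_start[j], prim_start[j] + prim_count[j]):
                    b = pexp[jp]
                    cb = pcoef[jp]
                    p = a + b
                    pp_p[ij, n] = p
                    for d in range(3):
                        pp_P[ij, n, d] = (a * centers[i, d] + b * centers[j, d]) / p
                        _e_table(powers[i, d], powers[j, d], a, b,
                                 centers[i, d] - centers[j, d], E)
                        for t in range(pp_t[ij, d] + 1):
                            pp_E[ij, n, d, t] = E[powers[i, d], powers[j, d], t]
                    # fold contraction coefficients into the x coefficients
                    for t in range(pp_t[ij, 0] + 1):
                        pp_E[ij, n, 0, t] *= ca * cb
                    n += 1
            pp_n[ij] = n
    return pp_n, pp_p, pp_P, pp_E, pp_t


@njit(cache=True)
def _quartet(ij, kl, pp_n, pp_p, pp_P, pp_E, pp_t, F, Rm):
    txb, tyb, tzb = pp_t[ij, 0], pp_t[ij, 1], pp_t[ij, 2]
    txk, tyk, tzk = pp_t[kl, 0], pp_t[kl, 1], pp_t[kl, 2]
    L = txb + tyb + tzb + txk + tyk + tzk
    val = 0.0
    for m in range(pp_n[ij]):
        p = pp_p[ij, m]
        for n in range(pp_n[kl]):
            q = pp_p[kl, n]
            theta = p * q / (p + q)
            X = pp_P[ij, m, 0] - pp_P[kl, n, 0]
            Y = pp_P[ij, m, 1] - pp_P[kl, n, 1]
            Z = pp_P[ij, m, 2] - pp_P[kl, n, 2]
            T2 = theta * (X * X + Y * Y + Z * Z)
            _boys(L, T2, F)
            _r_table(txb + txk, tyb + tyk, tzb + tzk, -2.0 * theta,
                     X, Y, Z, F, Rm)
            pref = 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))
            s = 0.0
            for t in range(txb + 1):
                ext = pp_E[ij, m, 0, t]
                if ext == 0.0:
                    continue
                for u in range(tyb + 1):
                    exu = ext * pp_E[ij, m, 1, u]
                    if exu == 0.0:
                        continue
                    for w in range(tzb + 1):
                        exw = exu * pp_E[ij, m, 2, w]
                        if exw == 0.0:
                            continue
                        for tt in range(txk + 1):
                            fxt = pp_E[kl, n, 0, tt]
                            if fxt == 0.0:
                                continue
                            sgn_t = -1.0 if (tt % 2) else 1.0
                            for uu in range(tyk + 1):
                                fxu = fxt * pp_E[kl, n, 1, uu]
                                if fxu == 0.0:
                                    continue
                                sgn_u = -sgn_t if (uu % 2) else sgn_t
                                for ww in range(tzk + 1):
                                    fxw = fxu * pp_E[kl, n, 2, ww]
                                    if fxw == 0.0:
                                        continue
                                    sgn = -sgn_u if (ww % 2) else sgn_u
                                    s += exw * fxw * sgn * Rm[0, t + tt, u + uu, w + ww]
            val += pref * s
    return val


@njit(cache=True)
def eri_compound(powers, centers, prim_start, prim_count, pexp, pcoef,
                 screen_tol=1e-12):
    """Full symmetric compound-index ERI matrix with Schwarz screening."""
    nao = powers.shape[0]
    npair = nao * (nao + 1) // 2
    pp_n, pp_p, pp_P, pp_E, pp_t = _pair_data(
        powers, centers, prim_start, prim_count, pexp, pcoef)
    Lmax = 12 * _MAXL
    F = np.empty(Lmax + 1)
    Rm = np.empty((Lmax + 1, 4 * _MAXL + 1, 4 * _MAXL + 1, 4 * _MAXL + 1))
    qs = np.empty(npair)
    for ij in range(npair):
        qs[ij] = math.sqrt(abs(_quartet(ij, ij, pp_n, pp_p, pp_P, pp_E, pp_t, F, Rm)))
    out = np.zeros((npair, npair))
    for ij in range(npair):
        for kl in range(ij + 1):
            if qs[ij] * qs[kl] < screen_tol:
                continue
            v = _quartet(ij, kl, pp_n, pp_p, pp_P, pp_E, pp_t, F, Rm)
            out[ij, kl] = v
            out[kl, ij] = v
    return out


@njit(cache=True)
def build_jk(eri, D):
    """Coulomb and exchange matrices from the compound ERI matrix."""
    nao = D.shape[0]
    J = np.zeros((nao, nao))
    K = np.zeros((nao, nao))
    for i in range(nao):
        for j in range(nao):
            ij = i * (i + 1) // 2 + j if i >= j else j * (j + 1) // 2 + i
            jv = 0.0
            kv = 0.0
            for k in range(nao):
                ik = i * (i + 1) // 2 + k if i >= k else k * (k + 1) // 2 + i
                for l in range(nao):
                    kl = k * (k + 1) // 2 + l if k >= l else l * (l + 1) // 2 + k
                    jl = j * (j + 1) // 2 + l if j >= l else l * (l + 1) // 2 + j
                    jv += eri[ij, kl] * D[k, l]
                    kv += eri[ik, jl] * D[k, l]
            J[i, j] = jv
            K[i, j] = kv
    return J, K
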