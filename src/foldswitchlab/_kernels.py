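"""Numba kernels for the coarse-grained potential and the Langevin integrator.

Bead layout: positions are a (3n, 3) array ordered [all CA | all CB | all O],
so bead indices are CA_i = i, CB_i = n + i, O_i = 2n + i.  All terms are
functions of internal distances (plus one scalar triple product for
chirality), which keeps the analytic gradients simple and exactly
rigid-motion invariant.

Energy components vector (length 11):
0 bonds, 1 chirality, 2 basin (helical/extended pseudo-dihedral wells),
3 excluded volume, 4 contact, 5 burial, 6 hbond additive, 7 hbond
cooperative, 8 memory, 9 umbrella, 10 separation restraint.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
from numba import njit

#: kcal/mol/Å force -> (g/mol) Å/fs^2 acceleration conversion
KFORCE = 4.184e-4
#: Boltzmann constant, kcal/mol/K
KB = 1.987204e-3

N_COMPS = 11
(C_BOND, C_CHIR, C_BASIN, C_EXCL, C_CONTACT, C_BURIAL, C_HB, C_HBCOOP,
 C_MEMORY, C_UMBRELLA, C_RESTRAINT) = range(N_COMPS)

# Amide-N reconstruction coefficients (ideal backbone geometry), rescaled
# to sum exactly to 1 so the virtual site is a true affine combination
# (exact translation invariance)
_NC_SUM = 0.48318 + 0.70328 - 0.18643
NC_PREV = 0.48318 / _NC_SUM
NC_SELF = 0.70328 / _NC_SUM
NC_OPREV = -0.18643 / _NC_SUM

ModelParams = namedtuple("ModelParams", [
    "n",
    # harmonic bonds
    "b_i", "b_j", "b_r0", "b_k",
    # excluded volume
    "e_i", "e_j", "e_r", "e_k",
    # chirality (flat-bottom on normalized triple product)
    "ch_ia", "ch_ib", "ch_ic", "ch_ig", "ch_cmin", "ch_k",
    # local basin wells on d(i,i+2) and d(i,i+3)
    "ra_i", "ra_eps", "ra_h13", "ra_s13", "ra_h14", "ra_s14",
    "ra_e13", "ra_es13", "ra_e14", "ra_es14",
    # contact (CB-CB, two wells)
    "c_i", "c_j", "c_g1", "c_g2", "c_w1", "c_w2",
    # burial (per-residue 3-class wells over CB density)
    "bu_gam", "bu_lo", "bu_hi", "bu_beta", "bu_a", "bu_b",
    # hydrogen bonding
    "hb_on", "hb_eps_h", "hb_eps_sheet", "hb_eps_coop",
    "hb_ron_h", "hb_sig_on", "hb_rca_h", "hb_sig_ca",
    "hb_ron_a", "hb_rca_a", "hb_min_sep",
    # fragment memory
    "m_i", "m_j", "m_r0", "m_sig", "m_w",
    # Q_diff spec + umbrella bias
    "q_i", "q_j", "q_rA", "q_rB", "q_sig", "q_qA", "q_qB", "q_norm",
    "umb_on", "umb_k", "umb_q0",
    # interdomain separation restraint
    "r_a", "r_b", "r_mind", "r_k",
])


@njit(cache=True, inline="always")
def _smoothstep(x):
    """Quintic smoothstep on [0, 1] and its derivative."""
    if x <= 0.0:
        return 0.0, 0.0
    if x >= 1.0:
        return 1.0, 0.0
    x2 = x * x
    s = x2 * x * (10.0 + x * (-15.0 + 6.0 * x))
    ds = 30.0 * x2 * (1.0 + x * (-2.0 + x))
    return s, ds


@njit(cache=True, inline="always")
def _well(r, a, b, c, d):
    """Compact-support window: 0 below a / above d, 1 on [b, c]."""
    if r <= a or r >= d:
        return 0.0, 0.0
    if r < b:
        s, ds = _smoothstep((r - a) / (b - a))
        return s, ds / (b - a)
    if r <= c:
        return 1.0, 0.0
    s, ds = _smoothstep((r - c) / (d - c))
    return 1.0 - s, -ds / (d - c)


@njit(cache=True)
def bonds_energy(pos, F, b_i, b_j, b_r0, b_k):
    e = 0.0
    for p in range(b_i.shape[0]):
        i, j = b_i[p], b_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - b_r0[p]
        e += 0.5 * b_k[p] * dr * dr
        g = b_k[p] * dr / r
        F[i, 0] -= g * dx
        F[i, 1] -= g * dy
        F[i, 2] -= g * dz
        F[j, 0] += g * dx
        F[j, 1] += g * dy
        F[j, 2] += g * dz
    return e


@njit(cache=True)
def excluded_energy(pos, F, e_i, e_j, e_r, e_k):
    e = 0.0
    for p in range(e_i.shape[0]):
        i, j = e_i[p], e_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < e_r[p]:
            d = e_r[p] - r
            e += e_k * d * d
            g = -2.0 * e_k * d / r  # dE/dr = -2 k d
            F[i, 0] -= g * dx
            F[i, 1] -= g * dy
            F[i, 2] -= g * dz
            F[j, 0] += g * dx
            F[j, 1] += g * dy
            F[j, 2] += g * dz
    return e


@njit(cache=True)
def chirality_energy(pos, F, ia, ib, ic, ig, cmin, kk):
    e = 0.0
    for p in range(ia.shape[0]):
        A, B, C, G = ia[p], ib[p], ic[p], ig[p]
        ax = pos[B, 0] - pos[A, 0]
        ay = pos[B, 1] - pos[A, 1]
        az = pos[B, 2] - pos[A, 2]
        bx = pos[C, 0] - pos[B, 0]
        by = pos[C, 1] - pos[B, 1]
        bz = pos[C, 2] - pos[B, 2]
        gx = pos[G, 0] - pos[B, 0]
        gy = pos[G, 1] - pos[B, 1]
        gz = pos[G, 2] - pos[B, 2]
        # det = a . (b x g)
        cx = by * gz - bz * gy
        cy = bz * gx - bx * gz
        cz = bx * gy - by * gx
        det = ax * cx + ay * cy + az * cz
        na = np.sqrt(ax * ax + ay * ay + az * az)
        nb = np.sqrt(bx * bx + by * by + bz * bz)
        ng = np.sqrt(gx * gx + gy * gy + gz * gz)
        norm = na * nb * ng
        c = det / norm
        if c >= cmin:
            continue
        e += 0.5 * kk * (c - cmin) * (c - cmin)
        dedc = kk * (c - cmin)
        # dc/da = (b x g)/norm - c a/|a|^2 ; cyclic for b, g
        bgx, bgy, bgz = cx, cy, cz
        gax = gy * az - gz * ay
        gay = gz * ax - gx * az
        gaz = gx * ay - gy * ax
        abx = ay * bz - az * by
        aby = az * bx - ax * bz
        abz = ax * by - ay * bx
        dca_x = bgx / norm - c * ax / (na * na)
        dca_y = bgy / norm - c * ay / (na * na)
        dca_z = bgz / norm - c * az / (na * na)
        dcb_x = gax / norm - c * bx / (nb * nb)
        dcb_y = gay / norm - c * by / (nb * nb)
        dcb_z = gaz / norm - c * bz / (nb * nb)
        dcg_x = abx / norm - c * gx / (ng * ng)
        dcg_y = aby / norm - c * gy / (ng * ng)
        dcg_z = abz / norm - c * gz / (ng * ng)
        # distribute: a = B - A, b = C - B, g = G - B
        F[A, 0] += dedc * dca_x
        F[A, 1] += dedc * dca_y
        F[A, 2] += dedc * dca_z
        F[B, 0] -= dedc * (dca_x - dcb_x - dcg_x)
        F[B, 1] -= dedc * (dca_y - dcb_y - dcg_y)
        F[B, 2] -= dedc * (dca_z - dcb_z - dcg_z)
        F[C, 0] -= dedc * dcb_x
        F[C, 1] -= dedc * dcb_y
        F[C, 2] -= dedc * dcb_z
        F[G, 0] -= dedc * dcg_x
        F[G, 1] -= dedc * dcg_y
        F[G, 2] -= dedc * dcg_z
    return e


@njit(cache=True, inline="always")
def _gauss(r, r0, sig):
    z = (r - r0) / sig
    g = np.exp(-0.5 * z * z)
    dg = -z / sig * g
    return g, dg


@njit(cache=True, inline="always")
def _add_pair_force(F, i, j, g, pos):
    # adds force for dE/dr = g on pair (i, j)
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    gg = g / r
    F[i, 0] -= gg * dx
    F[i, 1] -= gg * dy
    F[i, 2] -= gg * dz
    F[j, 0] += gg * dx
    F[j, 1] += gg * dy
    F[j, 2] += gg * dz


@njit(cache=True, inline="always")
def _dist(pos, i, j):
    dx = pos[i, 0] - pos[j, 0]
    dy = pos[i, 1] - pos[j, 1]
    dz = pos[i, 2] - pos[j, 2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def basin_energy(pos, F, ra_i, eps, h13, s13, h14, s14, e13, es13, e14, es14):
    """Helical / extended basin wells on the (i,i+2) and (i,i+3) CA distances."""
    e = 0.0
    for p in range(ra_i.shape[0]):
        i = ra_i[p]
        r13 = _dist(pos, i, i + 2)
        r14 = _dist(pos, i, i + 3)
        gh13, dgh13 = _gauss(r13, h13, s13)
        gh14, dgh14 = _gauss(r14, h14, s14)
        ge13, dge13 = _gauss(r13, e13, es13)
        ge14, dge14 = _gauss(r14, e14, es14)
        e -= eps * (gh13 * gh14 + ge13 * ge14)
        d13 = -eps * (dgh13 * gh14 + dge13 * ge14)
        d14 = -eps * (gh13 * dgh14 + ge13 * dge14)
        _add_pair_force(F, i, i + 2, d13, pos)
        _add_pair_force(F, i, i + 3, d14, pos)
    return e


@njit(cache=True)
def contact_energy(pos, F, c_i, c_j, g1, g2, w1, w2):
    e = 0.0
    for p in range(c_i.shape[0]):
        i, j = c_i[p], c_j[p]
        r = _dist(pos, i, j)
        t1, dt1 = _well(r, w1[0], w1[1], w1[2], w1[3])
        t2, dt2 = _well(r, w2[0], w2[1], w2[2], w2[3])
        e += g1[p] * t1 + g2[p] * t2
        dedr = g1[p] * dt1 + g2[p] * dt2
        if dedr != 0.0:
            _add_pair_force(F, i, j, dedr, pos)
    return e


@njit(cache=True)
def burial_energy(pos, F, n, gam, lo, hi, beta, a, b):
    """Three-class burial wells over a smooth CB-neighbour density."""
    if gam.shape[0] == 0:
        return 0.0
    rho = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if abs(i - j) < 2 or j == i:
                continue
            r = _dist(pos, n + i, n + j)
            if r < b:
                if r <= a:
                    rho[i] += 1.0
                else:
                    s, _ = _smoothstep((r - a) / (b - a))
                    rho[i] += 1.0 - s
    e = 0.0
    dvdrho = np.zeros(n)
    for i in range(n):
        for c in range(3):
            tlo = np.tanh(beta * (rho[i] - lo[c]))
            thi = np.tanh(beta * (rho[i] - hi[c]))
            w = 0.5 * (tlo - thi)
            e += gam[i, c] * w
            dw = 0.5 * beta * ((1.0 - tlo * tlo) - (1.0 - thi * thi))
            dvdrho[i] += gam[i, c] * dw
    for i in range(n):
        for j in range(i + 2, n):
            r = _dist(pos, n + i, n + j)
            if a < r < b:
                _, ds = _smoothstep((r - a) / (b - a))
                drho = -ds / (b - a)
                dedr = (dvdrho[i] + dvdrho[j]) * drho
                _add_pair_force(F, n + i, n + j, dedr, pos)
    return e


@njit(cache=True)
def _amide_n(pos, n):
    """Virtual amide N for residues 1..n-1 (row 0 unused)."""
    npos = np.zeros((n, 3))
    for j in range(1, n):
        for d in range(3):
            npos[j, d] = (NC_PREV * pos[j - 1, d] + NC_SELF * pos[j, d]
                          + NC_OPREV * pos[2 * n + j - 1, d])
    return npos


@njit(cache=True, inline="always")
def _spread_n_grad(F, n, j, gx, gy, gz):
    """Distribute a gradient on virtual N_j onto its parent beads."""
    F[j - 1, 0] -= NC_PREV * gx
    F[j - 1, 1] -= NC_PREV * gy
    F[j - 1, 2] -= NC_PREV * gz
    F[j, 0] -= NC_SELF * gx
    F[j, 1] -= NC_SELF * gy
    F[j, 2] -= NC_SELF * gz
    F[2 * n + j - 1, 0] -= NC_OPREV * gx
    F[2 * n + j - 1, 1] -= NC_OPREV * gy
    F[2 * n + j - 1, 2] -= NC_OPREV * gz


@njit(cache=True, inline="always")
def _vdist(pos_i, npos_j):
    dx = pos_i[0] - npos_j[0]
    dy = pos_i[1] - npos_j[1]
    dz = pos_i[2] - npos_j[2]
    return np.sqrt(dx * dx + dy * dy + dz * dz), dx, dy, dz


@njit(cache=True)
def hbond_energy(pos, F, n, eps_h, eps_sheet, eps_coop,
                 ron_h, sig_on, rca_h, sig_ca, ron_a, rca_a,
                 min_sep):
    """Helical and sheet O···N wells plus a >= 3-rung cooperative sheet term.

    Rung occupancies u(i,j) in [0, 1] are products of Gaussian factors of
    the two O···N distances and of the CA-CA registry distance; cooperative
    energy sums products of three consecutive rungs, so isolated rungs and
    2-rung ladders contribute exactly zero cooperativity.
    """
    npos = _amide_n(pos, n)
    e_add = 0.0
    e_coop = 0.0

    # --- helical registry: O_i ... N_{i+4}
    for i in range(n - 4):
        j = i + 4
        r_on, _, _, _ = _vdist(pos[2 * n + i], npos[j])
        r_ca = _dist(pos, i, j)
        g1, dg1 = _gauss(r_on, ron_h, sig_on)
        g2, dg2 = _gauss(r_ca, rca_h, sig_ca)
        e_add -= eps_h * g1 * g2
        # force through O_i - N_j distance
        d_on = -eps_h * dg1 * g2
        if d_on != 0.0:
            rr, dx, dy, dz = _vdist(pos[2 * n + i], npos[j])
            gx, gy, gz = d_on * dx / rr, d_on * dy / rr, d_on * dz / rr
            F[2 * n + i, 0] -= gx
            F[2 * n + i, 1] -= gy
            F[2 * n + i, 2] -= gz
            _spread_n_grad(F, n, j, -gx, -gy, -gz)
        d_ca = -eps_h * g1 * dg2
        if d_ca != 0.0:
            _add_pair_force(F, i, j, d_ca, pos)

    # --- sheet rungs
    U = np.zeros((n, n))
    for i in range(1, n):
        for j in range(i + min_sep, n):
            # antiparallel: O_i...N_j and O_j...N_i both short
            r1, _, _, _ = _vdist(pos[2 * n + i], npos[j])
            r2, _, _, _ = _vdist(pos[2 * n + j], npos[i])
            rca = _dist(pos, i, j)
            if rca > rca_a + 4.0:
                continue
            ga1, _ = _gauss(r1, ron_a, sig_on)
            ga2, _ = _gauss(r2, ron_a, sig_on)
            gac, _ = _gauss(rca, rca_a, sig_ca)
            U[i, j] = ga1 * ga2 * gac
    # additive + cooperative adjoint on U
    A = np.zeros((n, n))
    for i in range(1, n):
        for j in range(i + min_sep, n):
            if U[i, j] > 0.0:
                e_add -= eps_sheet * U[i, j]
                A[i, j] -= eps_sheet
    for i in range(1, n - 2):
        for j in range(i + min_sep + 4, n):
            # antiparallel ladder triplet (i,j), (i+1,j-1), (i+2,j-2)
            u1 = U[i, j]
            u2 = U[i + 1, j - 1]
            u3 = U[i + 2, j - 2]
            p = u1 * u2 * u3
            if p > 0.0:
                e_coop -= eps_coop * p
                A[i, j] -= eps_coop * u2 * u3
                A[i + 1, j - 1] -= eps_coop * u1 * u3
                A[i + 2, j - 2] -= eps_coop * u1 * u2
    for i in range(1, n - 2):
        for j in range(i + min_sep, n - 2):
            # parallel ladder triplet (i,j), (i+1,j+1), (i+2,j+2)
            u1 = U[i, j]
            u2 = U[i + 1, j + 1]
            u3 = U[i + 2, j + 2]
            p = u1 * u2 * u3
            if p > 0.0:
                e_coop -= eps_coop * p
                A[i, j] -= eps_coop * u2 * u3
                A[i + 1, j + 1] -= eps_coop * u1 * u3
                A[i + 2, j + 2] -= eps_coop * u1 * u2
    # backpropagate dE/dU through the three Gaussian factors
    for i in range(1, n):
        for j in range(i + min_sep, n):
            if A[i, j] == 0.0 or U[i, j] <= 0.0:
                continue
            aij = A[i, j]
            r1, dx1, dy1, dz1 = _vdist(pos[2 * n + i], npos[j])
            r2, dx2, dy2, dz2 = _vdist(pos[2 * n + j], npos[i])
            rca = _dist(pos, i, j)
            # du/dr = u * dln(g)/dr = -u (r - r0)/sig^2
            u = U[i, j]
            dedr1 = aij * u * (-(r1 - ron_a) / (sig_on * sig_on))
            dedr2 = aij * u * (-(r2 - ron_a) / (sig_on * sig_on))
            dedrc = aij * u * (-(rca - rca_a) / (sig_ca * sig_ca))
            gx = dedr1 * dx1 / r1
            gy = dedr1 * dy1 / r1
            gz = dedr1 * dz1 / r1
            F[2 * n + i, 0] -= gx
            F[2 * n + i, 1] -= gy
            F[2 * n + i, 2] -= gz
            _spread_n_grad(F, n, j, -gx, -gy, -gz)
            gx = dedr2 * dx2 / r2
            gy = dedr2 * dy2 / r2
            gz = dedr2 * dz2 / r2
            F[2 * n + j, 0] -= gx
            F[2 * n + j, 1] -= gy
            F[2 * n + j, 2] -= gz
            _spread_n_grad(F, n, i, -gx, -gy, -gz)
            _add_pair_force(F, i, j, dedrc, pos)
    return e_add, e_coop


@njit(cache=True)
def memory_energy(pos, F, m_i, m_j, m_r0, m_sig, m_w):
    e = 0.0
    for p in range(m_i.shape[0]):
        i, j = m_i[p], m_j[p]
        r = _dist(pos, i, j)
        g, dg = _gauss(r, m_r0[p], m_sig[p])
        e -= m_w[p] * g
        dedr = -m_w[p] * dg
        if dedr != 0.0:
            _add_pair_force(F, i, j, dedr, pos)
    return e


@njit(cache=True)
def qdiff_value(pos, q_i, q_j, q_rA, q_rB, q_sig, q_qA, q_qB, q_norm):
    q = 0.0
    for p in range(q_i.shape[0]):
        r = _dist(pos, q_i[p], q_j[p])
        zA = (r - q_rA[p]) / q_sig[p]
        zB = (r - q_rB[p]) / q_sig[p]
        q += np.exp(-0.5 * zA * zA) + 1.0 - np.exp(-0.5 * zB * zB)
    q *= q_norm
    return (q - q_qA) / (q_qB - q_qA)


@njit(cache=True)
def umbrella_energy(pos, F, q_i, q_j, q_rA, q_rB, q_sig, q_qA, q_qB, q_norm,
                    umb_k, umb_q0):
    qdiff = qdiff_value(pos, q_i, q_j, q_rA, q_rB, q_sig, q_qA, q_qB, q_norm)
    dq = qdiff - umb_q0
    e = 0.5 * umb_k * dq * dq
    pref = umb_k * dq * q_norm / (q_qB - q_qA)
    for p in range(q_i.shape[0]):
        r = _dist(pos, q_i[p], q_j[p])
        s2 = q_sig[p] * q_sig[p]
        zA = (r - q_rA[p])
        zB = (r - q_rB[p])
        dqdr = (-zA / s2 * np.exp(-0.5 * zA * zA / s2)
                + zB / s2 * np.exp(-0.5 * zB * zB / s2))
        dedr = pref * dqdr
        if dedr != 0.0:
            _add_pair_force(F, q_i[p], q_j[p], dedr, pos)
    return e, qdiff


@njit(cache=True)
def restraint_energy(pos, F, r_a, r_b, r_mind, r_k):
    na, nb = r_a.shape[0], r_b.shape[0]
    cax = cay = caz = 0.0
    for p in range(na):
        cax += pos[r_a[p], 0]
        cay += pos[r_a[p], 1]
        caz += pos[r_a[p], 2]
    cbx = cby = cbz = 0.0
    for p in range(nb):
        cbx += pos[r_b[p], 0]
        cby += pos[r_b[p], 1]
        cbz += pos[r_b[p], 2]
    cax /= na
    cay /= na
    caz /= na
    cbx /= nb
    cby /= nb
    cbz /= nb
    dx, dy, dz = cax - cbx, cay - cby, caz - cbz
    d = np.sqrt(dx * dx + dy * dy + dz * dz)
    if d >= r_mind:
        return 0.0
    e = 0.5 * r_k * (d - r_mind) * (d - r_mind)
    dedd = r_k * (d - r_mind)
    gx, gy, gz = dedd * dx / d, dedd * dy / d, dedd * dz / d
    for p in range(na):
        F[r_a[p], 0] -= gx / na
        F[r_a[p], 1] -= gy / na
        F[r_a[p], 2] -= gz / na
    for p in range(nb):
        F[r_b[p], 0] += gx / nb
        F[r_b[p], 1] += gy / nb
        F[r_b[p], 2] += gz / nb
    return e


@njit(cache=True)
def total_force(pos, F, P):
    """Accumulate all enabled terms; returns (components, qdiff)."""
    comps = np.zeros(N_COMPS)
    comps[C_BOND] = bonds_energy(pos, F, P.b_i, P.b_j, P.b_r0, P.b_k)
    comps[C_CHIR] = chirality_energy(pos, F, P.ch_ia, P.ch_ib, P.ch_ic,
                                     P.ch_ig, P.ch_cmin, P.ch_k)
    comps[C_BASIN] = basin_energy(pos, F, P.ra_i, P.ra_eps, P.ra_h13, P.ra_s13,
                                  P.ra_h14, P.ra_s14, P.ra_e13, P.ra_es13,
                                  P.ra_e14, P.ra_es14)
    comps[C_EXCL] = excluded_energy(pos, F, P.e_i, P.e_j, P.e_r, P.e_k)
    comps[C_CONTACT] = contact_energy(pos, F, P.c_i, P.c_j, P.c_g1, P.c_g2,
                                      P.c_w1, P.c_w2)
    comps[C_BURIAL] = burial_energy(pos, F, P.n, P.bu_gam, P.bu_lo, P.bu_hi,
                                    P.bu_beta, P.bu_a, P.bu_b)
    if P.hb_on != 0:
        e_add, e_coop = hbond_energy(
            pos, F, P.n, P.hb_eps_h, P.hb_eps_sheet, P.hb_eps_coop,
            P.hb_ron_h, P.hb_sig_on, P.hb_rca_h, P.hb_sig_ca,
            P.hb_ron_a, P.hb_rca_a, P.hb_min_sep)
        comps[C_HB] = e_add
        comps[C_HBCOOP] = e_coop
    comps[C_MEMORY] = memory_energy(pos, F, P.m_i, P.m_j, P.m_r0, P.m_sig,
                                    P.m_w)
    qdiff = np.nan
    if P.q_i.shape[0] > 0:
        if P.umb_on != 0:
            e_u, qdiff = umbrella_energy(pos, F, P.q_i, P.q_j, P.q_rA, P.q_rB,
                                         P.q_sig, P.q_qA, P.q_qB, P.q_norm,
                                         P.umb_k, P.umb_q0)
            comps[C_UMBRELLA] = e_u
        else:
            qdiff = qdiff_value(pos, P.q_i, P.q_j, P.q_rA, P.q_rB, P.q_sig,
                                P.q_qA, P.q_qB, P.q_norm)
    if P.r_a.shape[0] > 0:
        comps[C_RESTRAINT] = restraint_energy(pos, F, P.r_a, P.r_b, P.r_mind,
                                              P.r_k)
    return comps, qdiff


@njit(cache=True)
def baoab_chunk(pos, vel, mass, noise, dt, gamma, kbt, P):
    """Run len(noise) BAOAB Langevin steps in place; returns last components.

    ``kbt`` is a per-step array (kcal/mol) implementing the temperature
    schedule; ``noise`` is pre-drawn standard normal, shape (steps, nb, 3).
    """
    nb = pos.shape[0]
    F = np.zeros((nb, 3))
    comps, qdiff = total_force(pos, F, P)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    acc = KFORCE / mass
    for s in range(noise.shape[0]):
        vth = np.sqrt(kbt[s] * KFORCE / mass)
        for i in range(nb):
            for d in range(3):
                vel[i, d] += 0.5 * dt * F[i, d] * acc
                pos[i, d] += 0.5 * dt * vel[i, d]
                vel[i, d] = c1 * vel[i, d] + c2 * vth * noise[s, i, d]
                pos[i, d] += 0.5 * dt * vel[i, d]
        F[:] = 0.0
        comps, qdiff = total_force(pos, F, P)
        for i in range(nb):
            for d in range(3):
                vel[i, d] += 0.5 * dt * F[i, d] * acc
    return comps, qdiff


def empty_params(n: int) -> ModelParams:
    """All-terms-disabled parameter set for an n-residue chain."""
    zi = np.zeros(0, np.int64)
    zf = np.zeros(0, float)
    return ModelParams(
        n=n,
        b_i=zi, b_j=zi, b_r0=zf, b_k=zf,
        e_i=zi, e_j=zi, e_r=zf, e_k=0.0,
        ch_ia=zi, ch_ib=zi, ch_ic=zi, ch_ig=zi, ch_cmin=0.0, ch_k=0.0,
        ra_i=zi, ra_eps=0.0, ra_h13=0.0, ra_s13=1.0, ra_h14=0.0, ra_s14=1.0,
        ra_e13=0.0, ra_es13=1.0, ra_e14=0.0, ra_es14=1.0,
        c_i=zi, c_j=zi, c_g1=zf, c_g2=zf,
        c_w1=np.zeros(4), c_w2=np.zeros(4),
        bu_gam=np.zeros((0, 3)), bu_lo=np.zeros(3), bu_hi=np.zeros(3),
        bu_beta=1.0, bu_a=1.0, bu_b=2.0,
        hb_on=0, hb_eps_h=0.0, hb_eps_sheet=0.0, hb_eps_coop=0.0,
        hb_ron_h=3.0, hb_sig_on=0.6, hb_rca_h=6.2, hb_sig_ca=0.8,
        hb_ron_a=3.0, hb_rca_a=4.8, hb_min_sep=4,
        m_i=zi, m_j=zi, m_r0=zf, m_sig=zf, m_w=zf,
        q_i=zi, q_j=zi, q_rA=zf, q_rB=zf, q_sig=zf, q_qA=0.0, q_qB=1.0,
        q_norm=1.0,
        umb_on=0, umb_k=0.0, umb_q0=0.0,
        r_a=zi, r_b=zi, r_mind=0.0, r_k=0.0,
    )
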