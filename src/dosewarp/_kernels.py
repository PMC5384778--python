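"""Numba kernels for the intensity-registration inner loops.

The expensive pieces of FFD registration are (a) evaluating the dense
B-spline displacement field on the target grid, (b) pulling source samples
through the current transform, and (c) the central finite-difference gradient
of NMI with respect to the control-point displacements.  For (c), perturbing
one control point only moves the samples inside its 4x4x4-cell support, so
the kernel updates the joint histogram incrementally (and reverts it
afterwards) instead of re-binning the whole volume; the result equals a full
recomputation up to floating-point roundoff.

Basis weights are precomputed per voxel and per axis: ``W*[v, l]`` is the
cubic B-spline weight of control point ``c*b[v] + l`` (l = 0..3) at voxel
``v``; out-of-range control points contribute zero (virtual zero padding of
the lattice).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["ffd_grid_disp", "trilinear_grid", "joint_counts_grid", "nmi_fd_gradient",
           "entropy_nats"]


@njit(inline="always")
def _trilinear(src, p0, p1, p2, pad, clamped):
    """Trilinear sample; out-of-footprint points either return ``pad`` or are
    clamped to the boundary (``clamped`` true).  Clamping keeps a similarity
    objective continuous when sample positions cross the volume edge."""
    n0, n1, n2 = src.shape
    if clamped:
        if p0 < 0.0:
            p0 = 0.0
        elif p0 > n0 - 1.0:
            p0 = n0 - 1.0
        if p1 < 0.0:
            p1 = 0.0
        elif p1 > n1 - 1.0:
            p1 = n1 - 1.0
        if p2 < 0.0:
            p2 = 0.0
        elif p2 > n2 - 1.0:
            p2 = n2 - 1.0
    elif p0 < 0.0 or p0 > n0 - 1.0 or p1 < 0.0 or p1 > n1 - 1.0 or p2 < 0.0 or p2 > n2 - 1.0:
        return pad
    x0 = int(math.floor(p0))
    y0 = int(math.floor(p1))
    z0 = int(math.floor(p2))
    if x0 > n0 - 2:
        x0 = n0 - 2
    if y0 > n1 - 2:
        y0 = n1 - 2
    if z0 > n2 - 2:
        z0 = n2 - 2
    fx = p0 - x0
    fy = p1 - y0
    fz = p2 - z0
    lo = (src[x0, y0, z0] * (1.0 - fz) + src[x0, y0, z0 + 1] * fz) * (1.0 - fy) + (
        src[x0, y0 + 1, z0] * (1.0 - fz) + src[x0, y0 + 1, z0 + 1] * fz
    ) * fy
    hi = (src[x0 + 1, y0, z0] * (1.0 - fz) + src[x0 + 1, y0, z0 + 1] * fz) * (1.0 - fy) + (
        src[x0 + 1, y0 + 1, z0] * (1.0 - fz) + src[x0 + 1, y0 + 1, z0 + 1] * fz
    ) * fy
    return lo * (1.0 - fx) + hi * fx


@njit
def trilinear_grid(src, pos, pad, out, clamped=False):
    nx, ny, nz = out.shape
    for vx in range(nx):
        for vy in range(ny):
            for vz in range(nz):
                out[vx, vy, vz] = _trilinear(
                    src, pos[vx, vy, vz, 0], pos[vx, vy, vz, 1], pos[vx, vy, vz, 2],
                    pad, clamped,
                )


@njit
def ffd_grid_disp(C, Wx, cxb, Wy, cyb, Wz, czb, out):
    """Dense lattice displacement on a grid with separable precomputed weights."""
    ncx, ncy, ncz = C.shape[0], C.shape[1], C.shape[2]
    nx, ny, nz = out.shape[0], out.shape[1], out.shape[2]
    for vx in range(nx):
        bx = cxb[vx]
        for vy in range(ny):
            by = cyb[vy]
            for vz in range(nz):
                bz = czb[vz]
                u0 = 0.0
                u1 = 0.0
                u2 = 0.0
                for l in range(4):
                    i = bx + l
                    if i < 0 or i >= ncx:
                        continue
                    wl = Wx[vx, l]
                    for m in range(4):
                        j = by + m
                        if j < 0 or j >= ncy:
                            continue
                        wlm = wl * Wy[vy, m]
                        for n in range(4):
                            k = bz + n
                            if k < 0 or k >= ncz:
                                continue
                            w = wlm * Wz[vz, n]
                            u0 += w * C[i, j, k, 0]
                            u1 += w * C[i, j, k, 1]
                            u2 += w * C[i, j, k, 2]
                out[vx, vy, vz, 0] = u0
                out[vx, vy, vz, 1] = u1
                out[vx, vy, vz, 2] = u2


@njit
def joint_counts_grid(t_bin, s_bin, bins, joint, marg_b):
    """Accumulate joint and source-marginal counts; t_bin < 0 marks excluded voxels."""
    n = 0
    flat_t = t_bin.ravel()
    flat_s = s_bin.ravel()
    for v in range(flat_t.shape[0]):
        tb = flat_t[v]
        if tb < 0:
            continue
        sb = flat_s[v]
        joint[tb, sb] += 1
        marg_b[sb] += 1
        n += 1
    return n


@njit(inline="always")
def _nlogn_1d(counts):
    s = 0.0
    for i in range(counts.shape[0]):
        c = counts[i]
        if c > 0:
            s += c * math.log(c)
    return s


@njit(inline="always")
def _nlogn_2d(counts):
    s = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            c = counts[i, j]
            if c > 0:
                s += c * math.log(c)
    return s


@njit
def entropy_nats(counts_flat, n_samples):
    """H = log(N) - sum(n log n)/N in nats, from integer counts."""
    if n_samples <= 0:
        return 0.0
    return math.log(n_samples) - _nlogn_1d(counts_flat) / n_samples


@njit
def nmi_fd_gradient(
    src, cur_pos, s_bin, t_bin, joint, marg_b, n_samples, h_a,
    lo_b, inv_w_b, bins, pad, h, inv_sp,
    Wx, cxb, Wy, cyb, Wz, czb,
    vlox, vhix, vloy, vhiy, vloz, vhiz,
    free, grad, buf_ob, buf_nb, buf_tb, clamped=False,
):
    """Central-difference NMI gradient w.r.t. free control-point displacements.

    ``grad`` is written in place, zero for frozen control points.  The joint
    histogram and source marginal are mutated during each one-sided
    perturbation and restored exactly (integer counts) before returning.
    """
    ncx, ncy, ncz = free.shape
    log_n = math.log(n_samples)
    for ci in range(ncx):
        for cj in range(ncy):
            for ck in range(ncz):
                if free[ci, cj, ck] == 0:
                    grad[ci, cj, ck, 0] = 0.0
                    grad[ci, cj, ck, 1] = 0.0
                    grad[ci, cj, ck, 2] = 0.0
                    continue
                for d in range(3):
                    nmi_side = np.empty(2)
                    for side in range(2):
                        sign = 1.0 if side == 0 else -1.0
                        delta = sign * h * inv_sp[d]
                        nchanged = 0
                        for vx in range(vlox[ci], vhix[ci]):
                            lx = ci - cxb[vx]
                            wxv = Wx[vx, lx]
                            if wxv == 0.0:
                                continue
                            for vy in range(vloy[cj], vhiy[cj]):
                                ly = cj - cyb[vy]
                                wyv = wxv * Wy[vy, ly]
                                if wyv == 0.0:
                                    continue
                                for vz in range(vloz[ck], vhiz[ck]):
                                    tb = t_bin[vx, vy, vz]
                                    if tb < 0:
                                        continue
                                    lz = ck - czb[vz]
                                    w = wyv * Wz[vz, lz]
                                    if w == 0.0:
                                        continue
                                    p0 = cur_pos[vx, vy, vz, 0]
                                    p1 = cur_pos[vx, vy, vz, 1]
                                    p2 = cur_pos[vx, vy, vz, 2]
                                    if d == 0:
                                        p0 += delta * w
                                    elif d == 1:
                                        p1 += delta * w
                                    else:
                                        p2 += delta * w
                                    s = _trilinear(src, p0, p1, p2, pad, clamped)
                                    nb = int(math.floor((s - lo_b) * inv_w_b))
                                    if nb < 0:
                                        nb = 0
                                    elif nb > bins - 1:
                                        nb = bins - 1
                                    ob = s_bin[vx, vy, vz]
                                    if nb != ob:
                                        joint[tb, ob] -= 1
                                        joint[tb, nb] += 1
                                        marg_b[ob] -= 1
                                        marg_b[nb] += 1
                                        buf_ob[nchanged] = ob
                                        buf_nb[nchanged] = nb
                                        buf_tb[nchanged] = tb
                                        nchanged += 1
                        h_b = log_n - _nlogn_1d(marg_b) / n_samples
                        h_ab = log_n - _nlogn_2d(joint) / n_samples
                        if h_ab > 0.0:
                            nmi_side[side] = (h_a + h_b) / h_ab
                        else:
                            nmi_side[side] = 2.0
                        for r in range(nchanged - 1, -1, -1):
                            ob = buf_ob[r]
                            nb = buf_nb[r]
                            tb = buf_tb[r]
                            joint[tb, ob] += 1
                            joint[tb, nb] -= 1
                            marg_b[ob] += 1
                            marg_b[nb] -= 1
                    grad[ci, cj, ck, d] = (nmi_side[0] - nmi_side[1]) / (2.0 * h)
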