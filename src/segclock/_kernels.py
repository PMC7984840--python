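"""Compiled inner loop of the simulator.

One numba kernel advances the full particle/oscillator state by a block of
Euler–Maruyama steps.  Neighbor search uses a linked-cell grid with bin size
dc, rebuilt every step, which gives exact cutoff semantics.  The kernel
mirrors, term by term, the reference numpy implementations in
:mod:`segclock.mechanics` and :mod:`segclock.phase_dynamics`; an integration
test holds the two paths together.

All scalar parameters travel in a single float64 vector ``P`` indexed by the
constants below (engine builds it via :func:`pack_params`).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --- indices into the packed parameter vector ------------------------------
P_R0 = 0      # tube radius at t=0 (μm)
P_RTOR = 1    # torus core radius R (μm)
P_XC = 2
P_YC = 3
P_ZC = 4
P_LX = 5
P_MU = 6
P_DC = 7
P_MUB = 8
P_RB = 9
P_VS = 10
P_XV = 11
P_H = 12
P_DPHI = 13
P_VA = 14
P_VPE = 15
P_VPL = 16
P_XQ = 17
P_TG = 18
P_OM0 = 19
P_SIG = 20
P_KSH = 21
P_KAP0 = 22
P_KAPS = 23
P_TWASH = 24
P_DTH = 25
P_UA = 26
P_SR = 27
P_RFLOOR = 28
P_DT = 29
N_PARAMS = 30

# Fixed unit vector used to separate exactly coincident cells (seeded draw).
_U0 = np.random.default_rng(12345).standard_normal(3)
_U0 /= np.linalg.norm(_U0)
U0X, U0Y, U0Z = float(_U0[0]), float(_U0[1]), float(_U0[2])

_POLE_EPS = 1e-6
_TWO_PI = 2.0 * np.pi


def pack_params(geom, mech, phase, program, dt: float) -> np.ndarray:
    """Flatten the parameter dataclasses into the kernel's float64 vector."""
    P = np.zeros(N_PARAMS)
    P[P_R0] = geom.r0
    P[P_RTOR] = geom.R
    P[P_XC] = geom.Xc
    P[P_YC] = geom.Yc
    P[P_ZC] = geom.Zc
    P[P_LX] = geom.Lx
    P[P_MU] = mech.mu
    P[P_DC] = mech.dc
    P[P_MUB] = mech.mu_b
    P[P_RB] = mech.r_b
    P[P_VS] = mech.vs
    P[P_XV] = mech.Xv
    P[P_H] = mech.h
    P[P_DPHI] = mech.Dphi
    P[P_VA] = mech.va
    P[P_VPE] = mech.vp_early
    P[P_VPL] = mech.vp_late
    P[P_XQ] = mech.xq
    P[P_TG] = mech.tg
    P[P_OM0] = phase.omega0
    P[P_SIG] = phase.sigma
    P[P_KSH] = phase.k
    P[P_KAP0] = phase.kappa0
    P[P_KAPS] = phase.kappa_s
    P[P_TWASH] = phase.t_washout
    P[P_DTH] = phase.Dtheta
    P[P_UA] = program.ua
    P[P_SR] = program.sr
    P[P_RFLOOR] = 2.0 * mech.dc
    P[P_DT] = dt
    return P


@njit(cache=True, fastmath=True)
def advance_block(  # noqa: C901 - one hot loop, deliberately monolithic
    pos,
    theta,
    pphi,
    ppsi,
    arrested,
    t_arrest,
    t0,
    nsteps,
    P,
    relax,
    noise_theta,
    noise_phi,
    noise_psi,
):
    """Advance all cells by ``nsteps`` steps of size P[P_DT] from time t0.

    State arrays are modified in place.  ``relax`` = 1 runs the
    initialization protocol: no advection, no phase update, and an extra
    frictionless wall at x = xa.  Noise arrays are (nsteps, n) standard
    normals (dummy (1, 1) arrays are fine when the matching intensity is 0).

    Returns (crossings, status): the number of cells newly arrested at the
    anterior boundary (removal events for the density bookkeeping) and 0 on
    success / 1 if a non-finite position or phase appeared.
    """
    n = pos.shape[0]
    r0_ = P[P_R0]
    R_ = P[P_RTOR]
    Xc_ = P[P_XC]
    Yc_ = P[P_YC]
    Zc_ = P[P_ZC]
    Lx_ = P[P_LX]
    mu_ = P[P_MU]
    mub_ = P[P_MUB]
    rb_ = P[P_RB]
    vs_ = P[P_VS]
    Xv_ = P[P_XV]
    h_ = P[P_H]
    Dphi_ = P[P_DPHI]
    va_ = P[P_VA]
    vpe_ = P[P_VPE]
    vpl_ = P[P_VPL]
    xq_ = P[P_XQ]
    tg_ = P[P_TG]
    om0_ = P[P_OM0]
    sig_ = P[P_SIG]
    ksh_ = P[P_KSH]
    kap0_ = P[P_KAP0]
    kaps_ = P[P_KAPS]
    twash_ = P[P_TWASH]
    dth_ = P[P_DTH]
    ua_ = P[P_UA]
    sr_ = P[P_SR]
    rfloor_ = P[P_RFLOOR]
    dt = P[P_DT]
    dc = P[P_DC]
    dc2 = dc * dc
    crossings = 0
    status = 0

    vel = np.empty((n, 3))
    dthe = np.empty(n)
    binid = np.empty(n, np.int64)
    sid = np.empty(n, np.int32)
    spx = np.empty(n)
    spy = np.empty(n)
    spz = np.empty(n)
    sinth = np.empty(n)
    costh = np.empty(n)
    # Verlet neighbor list (CSR): rebuilt every few steps with a skin margin
    # wide enough that no pair can close from beyond dc+skin to dc in
    # between; the exact cutoff d <= dc is still applied every step.
    skin = 0.2 * dc
    cut2 = (dc + skin) * (dc + skin)
    rebuild_every = 5
    cap = 64 * n
    nlist = np.empty(cap, np.int32)
    noff = np.zeros(n + 1, np.int64)

    for s_ in range(nsteps):
        t = t0 + s_ * dt
        xa = ua_ * t
        L = Lx_ - xa
        rcur = r0_ - sr_ * t
        if rcur < rfloor_:
            rcur = rfloor_
        if relax == 1:
            kap = 0.0
        elif t < twash_:
            kap = 0.0
        else:
            kap = kaps_ * t + kap0_
        vp = vpe_ if t < tg_ else vpl_

        if s_ % rebuild_every == 0:
            # counting-sort cells into a CSR cell grid (sorted coordinate
            # copies make the scans contiguous), then harvest candidates
            xmin = xa - dc - 1.0
            xmax = Lx_ + r0_ + 1.0
            ymin = -r0_ - 1.0
            ymax = 2.0 * Yc_ + r0_ + 1.0
            zmin = -r0_ - 1.0
            zmax = 2.0 * r0_ + r0_ + 1.0
            nx = int((xmax - xmin) / dc) + 1
            ny = int((ymax - ymin) / dc) + 1
            nz = int((zmax - zmin) / dc) + 1
            nbins = nx * ny * nz
            counts = np.zeros(nbins + 1, np.int64)
            for i in range(n):
                # arrested cells beyond one diameter of xa cannot touch an
                # active cell; leave them out of the grid
                if arrested[i] == 1 and pos[i, 0] < xa - dc:
                    binid[i] = -1
                    continue
                bx = int((pos[i, 0] - xmin) / dc)
                by = int((pos[i, 1] - ymin) / dc)
                bz = int((pos[i, 2] - zmin) / dc)
                if bx < 0:
                    bx = 0
                elif bx >= nx:
                    bx = nx - 1
                if by < 0:
                    by = 0
                elif by >= ny:
                    by = ny - 1
                if bz < 0:
                    bz = 0
                elif bz >= nz:
                    bz = nz - 1
                b = (bx * ny + by) * nz + bz
                binid[i] = b
                counts[b + 1] += 1
            for b in range(nbins):
                counts[b + 1] += counts[b]
            fill = counts.copy()
            for i in range(n):
                b = binid[i]
                if b < 0:
                    continue
                k = fill[b]
                sid[k] = i
                spx[k] = pos[i, 0]
                spy[k] = pos[i, 1]
                spz[k] = pos[i, 2]
                fill[b] = k + 1
            ptr = 0
            for i in range(n):
                noff[i] = ptr
                if arrested[i] == 1:
                    continue
                b = binid[i]
                bz = b % nz
                by = (b // nz) % ny
                bx = b // (nz * ny)
                z_lo = bz - 1 if bz > 0 else 0
                z_hi = bz + 1 if bz < nz - 1 else nz - 1
                x = pos[i, 0]
                y = pos[i, 1]
                z = pos[i, 2]
                for cx in range(bx - 1, bx + 2):
                    if cx < 0 or cx >= nx:
                        continue
                    for cy in range(by - 1, by + 2):
                        if cy < 0 or cy >= ny:
                            continue
                        col = (cx * ny + cy) * nz
                        for k in range(counts[col + z_lo], counts[col + z_hi + 1]):
                            j = sid[k]
                            if j == i:
                                continue
                            dx0 = x - spx[k]
                            dy0 = y - spy[k]
                            dz0 = z - spz[k]
                            if dx0 * dx0 + dy0 * dy0 + dz0 * dz0 <= cut2:
                                if ptr >= cap:
                                    return crossings, 2
                                nlist[ptr] = j
                                ptr += 1
            noff[n] = ptr

        if kap > 0.0:
            for i in range(n):
                sinth[i] = np.sin(theta[i])
                costh[i] = np.cos(theta[i])

        # --- per-cell increments from the state at time t -------------------
        for i in range(n):
            if arrested[i] == 1:
                vel[i, 0] = -va_
                vel[i, 1] = 0.0
                vel[i, 2] = 0.0
                dthe[i] = 0.0
                continue
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            vx = 0.0
            vy = 0.0
            vz = 0.0
            if relax == 0:
                chi = (x - xa) / L
                if chi <= xq_:
                    v = -((va_ - vp * (1.0 - xq_)) / xq_) * chi + va_
                else:
                    v = -vp * chi + vp
                vx -= v
            xbar = (x - xa) / L
            g = (1.0 - xbar) / Xv_
            if h_ == 3.0:
                gh = g * g * g
            else:
                gh = g ** h_
            v0 = vs_ / (1.0 + gh)
            sphi = np.sin(pphi[i])
            vx += v0 * sphi * np.cos(ppsi[i])
            vy += v0 * sphi * np.sin(ppsi[i])
            vz += v0 * np.cos(pphi[i])
            if Dphi_ > 0.0:
                # polarity walk (tangent-plane kick + renormalization); no
                # cell reads another's polarity, so the update can happen
                # here, after this cell's n_i was used above
                root = np.sqrt(2.0 * Dphi_ * dt)
                nx0 = sphi * np.cos(ppsi[i])
                ny0 = sphi * np.sin(ppsi[i])
                nz0 = np.cos(pphi[i])
                xi_a = noise_psi[s_, i]  # along m_x (azimuthal)
                xi_p = noise_phi[s_, i]  # along m_y = m_x × n (unit vector)
                # φ is clamped to [1e-6, π - 1e-6], so sphi never vanishes
                nx1 = nx0 + root * (xi_a * (ny0 / sphi) + xi_p * (-nx0 * nz0 / sphi))
                ny1 = ny0 + root * (xi_a * (-nx0 / sphi) + xi_p * (-ny0 * nz0 / sphi))
                nz1 = nz0 + root * (xi_p * sphi)
                norm = np.sqrt(nx1 * nx1 + ny1 * ny1 + nz1 * nz1)
                nz1 /= norm
                if nz1 > 1.0:
                    nz1 = 1.0
                elif nz1 < -1.0:
                    nz1 = -1.0
                ph = np.arccos(nz1)
                if ph < _POLE_EPS:
                    ph = _POLE_EPS
                elif ph > np.pi - _POLE_EPS:
                    ph = np.pi - _POLE_EPS
                pphi[i] = ph
                ppsi[i] = np.arctan2(ny1, nx1) % _TWO_PI
            sin_i = sinth[i] if kap > 0.0 else 0.0
            cos_i = costh[i] if kap > 0.0 else 0.0

            csum = 0.0
            ccount = 0
            for k in range(noff[i], noff[i + 1]):
                j = nlist[k]
                dx0 = x - pos[j, 0]
                dy0 = y - pos[j, 1]
                dz0 = z - pos[j, 2]
                d2 = dx0 * dx0 + dy0 * dy0 + dz0 * dz0
                if d2 <= dc2:
                    d = np.sqrt(d2)
                    if d > 0.0:
                        f = mu_ * (1.0 - d / dc) / d
                        vx += f * dx0
                        vy += f * dy0
                        vz += f * dz0
                    else:
                        sgn = 1.0 if i < j else -1.0
                        vx += sgn * mu_ * U0X
                        vy += sgn * mu_ * U0Y
                        vz += sgn * mu_ * U0Z
                    if kap > 0.0:
                        csum += sinth[j] * cos_i - costh[j] * sin_i
                        ccount += 1

            # boundary confinement
            if x >= xa:
                if x >= Xc_:
                    dx0 = x - Xc_
                    dy0 = y - Yc_
                    s = np.sqrt(dx0 * dx0 + dy0 * dy0)
                    if s > 0.0:
                        cp = dx0 / s
                        sp = dy0 / s
                    else:
                        cp = 1.0
                        sp = 0.0
                    srad = s - R_
                    dz0 = z - Zc_
                    rho = np.sqrt(srad * srad + dz0 * dz0)
                    if rho > 0.0:
                        cq = srad / rho
                        sq = dz0 / rho
                    else:
                        cq = 1.0
                        sq = 0.0
                    gap = rcur - rho
                    vx += -mub_ * np.exp(-abs(cp * cq) * gap / rb_) * cp * cq
                    vy += -mub_ * np.exp(-abs(sp * cq) * gap / rb_) * sp * cq
                    vz += -mub_ * np.exp(-abs(sq) * gap / rb_) * sq
                else:
                    if y < Yc_:
                        ay = Yc_ - R_
                    else:
                        ay = Yc_ + R_
                    dy0 = y - ay
                    dz0 = z - Zc_
                    rho = np.sqrt(dy0 * dy0 + dz0 * dz0)
                    if rho > 0.0:
                        cq = dy0 / rho
                        sq = dz0 / rho
                    else:
                        cq = 1.0
                        sq = 0.0
                    gap = rcur - rho
                    vy += -mub_ * np.exp(-abs(cq) * gap / rb_) * cq
                    vz += -mub_ * np.exp(-abs(sq) * gap / rb_) * sq
            if relax == 1:
                vx += mub_ * np.exp(-(x - xa) / rb_)

            vel[i, 0] = vx
            vel[i, 1] = vy
            vel[i, 2] = vz

            if relax == 0:
                chi = (x - xa) / L
                if ksh_ == 0.0:
                    u = sig_ + (1.0 - sig_) * chi
                else:
                    u = sig_ + (1.0 - sig_) * (
                        -np.expm1(-ksh_ * chi)
                    ) / (-np.expm1(-ksh_))
                inc = om0_ * u * dt
                if ccount > 0 and kap > 0.0:
                    inc += kap * csum / ccount * dt
                if dth_ > 0.0:
                    inc += np.sqrt(2.0 * dth_ * dt) * noise_theta[s_, i]
                dthe[i] = inc
            else:
                dthe[i] = 0.0

        # --- apply the simultaneous update ---------------------------------
        tnext = t0 + (s_ + 1) * dt
        xan = ua_ * tnext
        rnext = r0_ - sr_ * tnext
        if rnext < rfloor_:
            rnext = rfloor_
        for i in range(n):
            pos[i, 0] += vel[i, 0] * dt
            pos[i, 1] += vel[i, 1] * dt
            pos[i, 2] += vel[i, 2] * dt
            if arrested[i] == 1:
                continue
            # wrap to [0, 2π); exact (Sterbenz) and identical to fmod here
            th = theta[i] + dthe[i]
            if th >= _TWO_PI:
                th -= _TWO_PI
            elif th < 0.0:
                th += _TWO_PI
            theta[i] = th
            if sr_ > 0.0:
                # pull cells stranded outside the shrinking wall back inside
                x = pos[i, 0]
                if x >= Xc_:
                    dx0 = x - Xc_
                    dy0 = pos[i, 1] - Yc_
                    s = np.sqrt(dx0 * dx0 + dy0 * dy0)
                    if s > 0.0:
                        cp = dx0 / s
                        sp = dy0 / s
                    else:
                        cp = 1.0
                        sp = 0.0
                    srad = s - R_
                    dz0 = pos[i, 2] - Zc_
                    rho = np.sqrt(srad * srad + dz0 * dz0)
                    if rho > rnext:
                        cq = srad / rho
                        sq = dz0 / rho
                        rnew = rnext - 2.0 * rb_
                        snew = R_ + rnew * cq
                        pos[i, 0] = Xc_ + snew * cp
                        pos[i, 1] = Yc_ + snew * sp
                        pos[i, 2] = Zc_ + rnew * sq
                elif x >= xan:
                    if pos[i, 1] < Yc_:
                        ay = Yc_ - R_
                    else:
                        ay = Yc_ + R_
                    dy0 = pos[i, 1] - ay
                    dz0 = pos[i, 2] - Zc_
                    rho = np.sqrt(dy0 * dy0 + dz0 * dz0)
                    if rho > rnext:
                        rnew = rnext - 2.0 * rb_
                        pos[i, 1] = ay + rnew * dy0 / rho
                        pos[i, 2] = Zc_ + rnew * dz0 / rho
            if relax == 0 and pos[i, 0] < xan:
                arrested[i] = 1
                t_arrest[i] = tnext
                crossings += 1
            if not (
                np.isfinite(pos[i, 0])
                and np.isfinite(pos[i, 1])
                and np.isfinite(pos[i, 2])
                and np.isfinite(theta[i])
            ):
                status = 1
        if status == 1:
            break
    return crossings, status
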