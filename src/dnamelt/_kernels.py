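"""Numba kernels: force evaluation, Langevin/Nosé-Hoover integration,
steepest-descent minimization and on-the-fly dissociation detection.

Everything here works on plain float64/int64 arrays in internal units
(Å, ps, amu, kJ/mol); the object-level API lives in :mod:`dnamelt.forcefield`
and :mod:`dnamelt.dynamics`.  Forces are accumulated pairwise (Newton's
third law enforced by construction) so the net force vanishes to round-off
for any configuration.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# acceleration [Å/ps²] = force [kJ/mol/Å] * KJ2MD / mass [amu]
KJ2MD = 100.0
MD2KJ = 0.01

# thermostat / integration modes
MODE_OFF = 0
MODE_LANGEVIN = 1
MODE_NH = 2
MODE_NHL = 3

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True, fastmath=True, error_model="numpy")
def eval_forces(
    pos, f,
    bond_idx, bond_r0, bond_k2, bond_k4,
    ang_idx, ang_t0, ang_k,
    dih_idx, dih_p0, dih_k,
    stk_idx, stk_sig, stk_eps,
    bp_idx, bp_sig, bp_eps, bp_alpha,
    ev_idx, ev_eps, ev_sig, ev_cut,
    pp_idx, elec_pref, kappa,
):
    """Accumulate forces into ``f`` (zeroed here) and return the energy
    decomposition ``(bond, angle, dihedral, stack, basepair, excl, elec)``
    in kJ/mol."""
    n = pos.shape[0]
    for i in range(n):
        f[i, 0] = 0.0
        f[i, 1] = 0.0
        f[i, 2] = 0.0

    e_bond = 0.0
    for m in range(bond_idx.shape[0]):
        i = bond_idx[m, 0]
        j = bond_idx[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        d = r - bond_r0[m]
        e_bond += bond_k2[m] * d * d + bond_k4[m] * d ** 4
        dv = (2.0 * bond_k2[m] * d + 4.0 * bond_k4[m] * d ** 3) / r
        fx = -dv * dx
        fy = -dv * dy
        fz = -dv * dz
        f[i, 0] += fx; f[i, 1] += fy; f[i, 2] += fz
        f[j, 0] -= fx; f[j, 1] -= fy; f[j, 2] -= fz

    e_ang = 0.0
    for m in range(ang_idx.shape[0]):
        i = ang_idx[m, 0]
        j = ang_idx[m, 1]
        k = ang_idx[m, 2]
        ax = pos[i, 0] - pos[j, 0]
        ay = pos[i, 1] - pos[j, 1]
        az = pos[i, 2] - pos[j, 2]
        bx = pos[k, 0] - pos[j, 0]
        by = pos[k, 1] - pos[j, 1]
        bz = pos[k, 2] - pos[j, 2]
        la = np.sqrt(ax * ax + ay * ay + az * az)
        lb = np.sqrt(bx * bx + by * by + bz * bz)
        cost = (ax * bx + ay * by + az * bz) / (la * lb)
        if cost > 1.0:
            cost = 1.0
        elif cost < -1.0:
            cost = -1.0
        theta = np.arccos(cost)
        sint = np.sqrt(1.0 - cost * cost)
        if sint < 1e-8:
            sint = 1e-8
        dth = theta - ang_t0[m]
        e_ang += ang_k[m] * dth * dth
        coef = -2.0 * ang_k[m] * dth / sint
        # d(theta)/d(ri) = (cost*a/la - b/lb) / (la*sint); force = -dV/dtheta * dtheta/dr
        fi_x = coef * (cost * ax / la - bx / lb) / la
        fi_y = coef * (cost * ay / la - by / lb) / la
        fi_z = coef * (cost * az / la - bz / lb) / la
        fk_x = coef * (cost * bx / lb - ax / la) / lb
        fk_y = coef * (cost * by / lb - ay / la) / lb
        fk_z = coef * (cost * bz / lb - az / la) / lb
        f[i, 0] += fi_x; f[i, 1] += fi_y; f[i, 2] += fi_z
        f[k, 0] += fk_x; f[k, 1] += fk_y; f[k, 2] += fk_z
        f[j, 0] -= fi_x + fk_x
        f[j, 1] -= fi_y + fk_y
        f[j, 2] -= fi_z + fk_z

    e_dih = 0.0
    for m in range(dih_idx.shape[0]):
        i = dih_idx[m, 0]
        j = dih_idx[m, 1]
        k = dih_idx[m, 2]
        l = dih_idx[m, 3]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        b3x = pos[l, 0] - pos[k, 0]
        b3y = pos[l, 1] - pos[k, 1]
        b3z = pos[l, 2] - pos[k, 2]
        # normals to the two planes
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        n1sq = n1x * n1x + n1y * n1y + n1z * n1z
        n2sq = n2x * n2x + n2y * n2y + n2z * n2z
        lb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1sq < 1e-12 or n2sq < 1e-12:
            continue  # collinear degenerate torsion carries no force
        # phi via atan2, sign convention fixed by this routine everywhere
        mx = n1y * n2z - n1z * n2y
        my = n1z * n2x - n1x * n2z
        mz = n1x * n2y - n1y * n2x
        sinp = (mx * b2x + my * b2y + mz * b2z) / lb2
        cosp = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sinp, cosp)
        dphi = phi - dih_p0[m]
        e_dih += dih_k[m] * (1.0 - np.cos(dphi))
        dv = dih_k[m] * np.sin(dphi)  # dV/dphi
        # gradient of phi (standard torsion derivative)
        gi = -lb2 / n1sq
        gl = lb2 / n2sq
        dpi_x = gi * n1x
        dpi_y = gi * n1y
        dpi_z = gi * n1z
        dpl_x = gl * n2x
        dpl_y = gl * n2y
        dpl_z = gl * n2z
        c12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (lb2 * lb2)
        c32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (lb2 * lb2)
        dpj_x = -(1.0 + c12) * dpi_x + c32 * dpl_x
        dpj_y = -(1.0 + c12) * dpi_y + c32 * dpl_y
        dpj_z = -(1.0 + c12) * dpi_z + c32 * dpl_z
        fi_x = -dv * dpi_x
        fi_y = -dv * dpi_y
        fi_z = -dv * dpi_z
        fj_x = -dv * dpj_x
        fj_y = -dv * dpj_y
        fj_z = -dv * dpj_z
        fl_x = -dv * dpl_x
        fl_y = -dv * dpl_y
        fl_z = -dv * dpl_z
        f[i, 0] += fi_x; f[i, 1] += fi_y; f[i, 2] += fi_z
        f[j, 0] += fj_x; f[j, 1] += fj_y; f[j, 2] += fj_z
        f[l, 0] += fl_x; f[l, 1] += fl_y; f[l, 2] += fl_z
        f[k, 0] -= fi_x + fj_x + fl_x
        f[k, 1] -= fi_y + fj_y + fl_y
        f[k, 2] -= fi_z + fj_z + fl_z

    e_stk = 0.0
    for m in range(stk_idx.shape[0]):
        i = stk_idx[m, 0]
        j = stk_idx[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        s = stk_sig[m] / r
        s10 = s ** 10
        s12 = s10 * s * s
        e_stk += stk_eps[m] * (5.0 * s12 - 6.0 * s10)
        dv = -60.0 * stk_eps[m] * (s12 - s10) / (r * r)  # dV/dr / r
        fx = -dv * dx
        fy = -dv * dy
        fz = -dv * dz
        f[i, 0] += fx; f[i, 1] += fy; f[i, 2] += fz
        f[j, 0] -= fx; f[j, 1] -= fy; f[j, 2] -= fz

    e_bp = 0.0
    for m in range(bp_idx.shape[0]):
        i = bp_idx[m, 0]
        j = bp_idx[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        ex = np.exp(-bp_alpha[m] * (r - bp_sig[m]))
        e_bp += bp_eps[m] * ((1.0 - ex) * (1.0 - ex) - 1.0)
        dv = 2.0 * bp_eps[m] * bp_alpha[m] * ex * (1.0 - ex) / r  # dV/dr / r
        fx = -dv * dx
        fy = -dv * dy
        fz = -dv * dz
        f[i, 0] += fx; f[i, 1] += fy; f[i, 2] += fz
        f[j, 0] -= fx; f[j, 1] -= fy; f[j, 2] -= fz

    e_ev = 0.0
    cut2 = ev_cut * ev_cut
    shift = (ev_sig / ev_cut) ** 12
    for m in range(ev_idx.shape[0]):
        i = ev_idx[m, 0]
        j = ev_idx[m, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= cut2:
            continue
        s2 = ev_sig * ev_sig / r2
        s12 = s2 * s2 * s2
        s12 = s12 * s12
        e_ev += ev_eps * (s12 - shift)
        dv = -12.0 * ev_eps * s12 / r2  # dV/dr / r
        fx = -dv * dx
        fy = -dv * dy
        fz = -dv * dz
        f[i, 0] += fx; f[i, 1] += fy; f[i, 2] += fz
        f[j, 0] -= fx; f[j, 1] -= fy; f[j, 2] -= fz

    e_el = 0.0
    if kappa > 0.0:
        for m in range(pp_idx.shape[0]):
            i = pp_idx[m, 0]
            j = pp_idx[m, 1]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            sc = elec_pref * np.exp(-r / kappa) / r
            e_el += sc
            dv = -sc * (1.0 / r + 1.0 / kappa) / r  # dV/dr / r
            fx = -dv * dx
            fy = -dv * dy
            fz = -dv * dz
            f[i, 0] += fx; f[i, 1] += fy; f[i, 2] += fz
            f[j, 0] -= fx; f[j, 1] -= fy; f[j, 2] -= fz

    return e_bond, e_ang, e_dih, e_stk, e_bp, e_ev, e_el


@njit(cache=True, error_model="numpy")
def nh_chain_half_step(vel, mass, vxi, xi, Q, kT, nf, dt2):
    """Half-step update of a Nosé-Hoover chain of arbitrary length,
    rescaling ``vel`` in place (Martyna-Tuckerman-Klein splitting)."""
    M = Q.shape[0]
    dt4 = 0.5 * dt2
    dt8 = 0.5 * dt4
    ke2 = 0.0
    for i in range(mass.shape[0]):
        ke2 += mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    ke2 *= MD2KJ  # = 2 * kinetic energy in kJ/mol

    if M > 1:
        g = (Q[M - 2] * vxi[M - 2] ** 2 - kT) / Q[M - 1]
    else:
        g = (ke2 - nf * kT) / Q[0]
    vxi[M - 1] += g * dt4
    for j in range(M - 2, -1, -1):
        vxi[j] *= np.exp(-dt8 * vxi[j + 1])
        if j == 0:
            g = (ke2 - nf * kT) / Q[0]
        else:
            g = (Q[j - 1] * vxi[j - 1] ** 2 - kT) / Q[j]
        vxi[j] += g * dt4
        vxi[j] *= np.exp(-dt8 * vxi[j + 1])

    scale = np.exp(-dt2 * vxi[0])
    for i in range(vel.shape[0]):
        vel[i, 0] *= scale
        vel[i, 1] *= scale
        vel[i, 2] *= scale
    ke2 *= scale * scale
    for j in range(M):
        xi[j] += dt2 * vxi[j]

    for j in range(M - 1):
        vxi[j] *= np.exp(-dt8 * vxi[j + 1])
        if j == 0:
            g = (ke2 - nf * kT) / Q[0]
        else:
            g = (Q[j - 1] * vxi[j - 1] ** 2 - kT) / Q[j]
        vxi[j] += g * dt4
        vxi[j] *= np.exp(-dt8 * vxi[j + 1])
    if M > 1:
        g = (Q[M - 2] * vxi[M - 2] ** 2 - kT) / Q[M - 1]
    else:
        g = (ke2 - nf * kT) / Q[0]
    vxi[M - 1] += g * dt4


@njit(cache=True)
def kinetic_energy(vel, mass):
    ke = 0.0
    for i in range(mass.shape[0]):
        ke += mass[i] * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    return 0.5 * ke * MD2KJ


@njit(cache=True, error_model="numpy")
def integrate(
    pos, vel, mass,
    bond_idx, bond_r0, bond_k2, bond_k4,
    ang_idx, ang_t0, ang_k,
    dih_idx, dih_p0, dih_k,
    stk_idx, stk_sig, stk_eps,
    bp_idx, bp_sig, bp_eps, bp_alpha,
    ev_idx, ev_eps, ev_sig, ev_cut,
    pp_idx, elec_pref, kappa,
    n_steps, dt, gamma, kT, mode, langevin_stride,
    vxi, xi, Q, nf,
    seed,
    check_every, persist, mon_a, mon_b, mon_thr, consec, ev_time, t_start,
    stop_when_melted,
    record_every, rec_t, rec_pos, rec_vel, rec_en,
):
    """Velocity-Verlet with a BAOAB-style Langevin substep and optional
    Nosé-Hoover chain coupling; detects basepair dissociation on the fly.

    Returns ``(steps_done, status, n_frames_recorded)``.  ``ev_time`` and
    ``consec`` are updated in place (first-passage, NaN = not dissociated).
    """
    np.random.seed(seed)
    n = pos.shape[0]
    f = np.zeros((n, 3))
    eb, ea, ed, es, ebp, eev, eel = eval_forces(
        pos, f,
        bond_idx, bond_r0, bond_k2, bond_k4,
        ang_idx, ang_t0, ang_k,
        dih_idx, dih_p0, dih_k,
        stk_idx, stk_sig, stk_eps,
        bp_idx, bp_sig, bp_eps, bp_alpha,
        ev_idx, ev_eps, ev_sig, ev_cut,
        pp_idx, elec_pref, kappa,
    )
    use_langevin = (mode == MODE_LANGEVIN or mode == MODE_NHL) and gamma > 0.0
    use_nh = mode == MODE_NH or mode == MODE_NHL
    if langevin_stride < 1:
        langevin_stride = 1
    # friction/noise applied every `langevin_stride` steps with the exactly
    # integrated Ornstein-Uhlenbeck decay over that interval
    c1 = np.exp(-gamma * dt * langevin_stride)
    c2sq = 1.0 - c1 * c1
    half = 0.5 * dt

    n_mon = mon_a.shape[0]
    n_events = 0
    for k in range(n_mon):
        if not np.isnan(ev_time[k]):
            n_events += 1

    frames = 0
    if record_every > 0:
        rec_t[0] = t_start
        for i in range(n):
            for d in range(3):
                rec_pos[0, i, d] = pos[i, d]
                rec_vel[0, i, d] = vel[i, d]
        rec_en[0, 0] = eb; rec_en[0, 1] = ea; rec_en[0, 2] = ed
        rec_en[0, 3] = es; rec_en[0, 4] = ebp; rec_en[0, 5] = eev
        rec_en[0, 6] = eel; rec_en[0, 7] = kinetic_energy(vel, mass)
        frames = 1

    steps_done = 0
    status = STATUS_OK
    for step in range(1, n_steps + 1):
        if use_nh:
            nh_chain_half_step(vel, mass, vxi, xi, Q, kT, nf, half)
        for i in range(n):
            inv = KJ2MD / mass[i] * half
            vel[i, 0] += f[i, 0] * inv
            vel[i, 1] += f[i, 1] * inv
            vel[i, 2] += f[i, 2] * inv
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        if use_langevin and step % langevin_stride == 0:
            for i in range(n):
                sig = np.sqrt(c2sq * kT * KJ2MD / mass[i])
                vel[i, 0] = c1 * vel[i, 0] + sig * np.random.standard_normal()
                vel[i, 1] = c1 * vel[i, 1] + sig * np.random.standard_normal()
                vel[i, 2] = c1 * vel[i, 2] + sig * np.random.standard_normal()
        for i in range(n):
            pos[i, 0] += half * vel[i, 0]
            pos[i, 1] += half * vel[i, 1]
            pos[i, 2] += half * vel[i, 2]
        eb, ea, ed, es, ebp, eev, eel = eval_forces(
            pos, f,
            bond_idx, bond_r0, bond_k2, bond_k4,
            ang_idx, ang_t0, ang_k,
            dih_idx, dih_p0, dih_k,
            stk_idx, stk_sig, stk_eps,
            bp_idx, bp_sig, bp_eps, bp_alpha,
            ev_idx, ev_eps, ev_sig, ev_cut,
            pp_idx, elec_pref, kappa,
        )
        for i in range(n):
            inv = KJ2MD / mass[i] * half
            vel[i, 0] += f[i, 0] * inv
            vel[i, 1] += f[i, 1] * inv
            vel[i, 2] += f[i, 2] * inv
        if use_nh:
            nh_chain_half_step(vel, mass, vxi, xi, Q, kT, nf, half)
        steps_done = step

        if check_every > 0 and step % check_every == 0:
            if not np.isfinite(pos[0, 0]):
                status = STATUS_NONFINITE
                break
            t_now = t_start + step * dt
            for k in range(n_mon):
                if not np.isnan(ev_time[k]):
                    continue
                a = mon_a[k]
                b = mon_b[k]
                dx = pos[a, 0] - pos[b, 0]
                dy = pos[a, 1] - pos[b, 1]
                dz = pos[a, 2] - pos[b, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                vr = (
                    (vel[a, 0] - vel[b, 0]) * dx
                    + (vel[a, 1] - vel[b, 1]) * dy
                    + (vel[a, 2] - vel[b, 2]) * dz
                )
                if r > mon_thr[k] and vr > 0.0:
                    consec[k] += 1
                    if consec[k] >= persist:
                        ev_time[k] = t_now - (persist - 1) * check_every * dt
                        n_events += 1
                else:
                    consec[k] = 0
            if stop_when_melted and n_events == n_mon:
                break

        if record_every > 0 and step % record_every == 0:
            rec_t[frames] = t_start + step * dt
            for i in range(n):
                for d in range(3):
                    rec_pos[frames, i, d] = pos[i, d]
                    rec_vel[frames, i, d] = vel[i, d]
            rec_en[frames, 0] = eb; rec_en[frames, 1] = ea
            rec_en[frames, 2] = ed; rec_en[frames, 3] = es
            rec_en[frames, 4] = ebp; rec_en[frames, 5] = eev
            rec_en[frames, 6] = eel
            rec_en[frames, 7] = kinetic_energy(vel, mass)
            frames += 1

    if status == STATUS_OK and not np.isfinite(pos[0, 0]):
        status = STATUS_NONFINITE
    return steps_done, status, frames


@njit(cache=True, error_model="numpy")
def minimize_sd(
    pos,
    bond_idx, bond_r0, bond_k2, bond_k4,
    ang_idx, ang_t0, ang_k,
    dih_idx, dih_p0, dih_k,
    stk_idx, stk_sig, stk_eps,
    bp_idx, bp_sig, bp_eps, bp_alpha,
    ev_idx, ev_eps, ev_sig, ev_cut,
    pp_idx, elec_pref, kappa,
    n_steps, step_size, force_tol,
):
    """Steepest descent with backtracking; energy never increases across
    accepted moves.  Returns (final_energy, iterations_used, max_force)."""
    n = pos.shape[0]
    f = np.zeros((n, 3))
    ft = np.zeros((n, 3))
    trial = np.zeros((n, 3))
    comp = eval_forces(
        pos, f,
        bond_idx, bond_r0, bond_k2, bond_k4,
        ang_idx, ang_t0, ang_k,
        dih_idx, dih_p0, dih_k,
        stk_idx, stk_sig, stk_eps,
        bp_idx, bp_sig, bp_eps, bp_alpha,
        ev_idx, ev_eps, ev_sig, ev_cut,
        pp_idx, elec_pref, kappa,
    )
    e = comp[0] + comp[1] + comp[2] + comp[3] + comp[4] + comp[5] + comp[6]
    step = step_size
    it = 0
    fmax = 0.0
    for it in range(1, n_steps + 1):
        fmax = 0.0
        for i in range(n):
            for d in range(3):
                a = abs(f[i, d])
                if a > fmax:
                    fmax = a
        if fmax < force_tol:
            break
        inv = step / fmax
        for i in range(n):
            for d in range(3):
                trial[i, d] = pos[i, d] + f[i, d] * inv
        comp = eval_forces(
            trial, ft,
            bond_idx, bond_r0, bond_k2, bond_k4,
            ang_idx, ang_t0, ang_k,
            dih_idx, dih_p0, dih_k,
            stk_idx, stk_sig, stk_eps,
            bp_idx, bp_sig, bp_eps, bp_alpha,
            ev_idx, ev_eps, ev_sig, ev_cut,
            pp_idx, elec_pref, kappa,
        )
        et = comp[0] + comp[1] + comp[2] + comp[3] + comp[4] + comp[5] + comp[6]
        if et <= e:
            for i in range(n):
                for d in range(3):
                    pos[i, d] = trial[i, d]
                    f[i, d] = ft[i, d]
            e = et
            step = min(step * 1.2, 0.5)
        else:
            step *= 0.5
            if step < 1e-10:
                break
    return e, it, fmax
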