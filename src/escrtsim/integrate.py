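"""Langevin (BAOAB) integration of membrane particles and rigid subunits.

Membrane particles carry a position, a velocity, an orientation (unit
normal) and an angular velocity; filament subunits are rigid bodies
(three collinear beads) integrated through their center of mass and a
unit quaternion.  The O-step uses the exact Ornstein-Uhlenbeck update,
so fluctuation-dissipation holds for any timestep.  Rotational inertia
is taken isotropic; this changes relaxation timescales slightly but not
the sampled (configurational) ensemble.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .forces import pair_nonbonded_forces, spring_forces

SUBUNIT_MASS = 3.0       # three unit-mass beads
SUBUNIT_INERTIA = 2.0    # two beads at +-1 sigma from the core
MEMBRANE_MASS = 1.0
MEMBRANE_INERTIA = 1.0


@njit(cache=True, inline="always")
def _quat_mul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@njit(cache=True, inline="always")
def _quat_rotate(q, v, out):
    # out = R(q) v
    w, x, y, z = q[0], q[1], q[2], q[3]
    tx = 2.0 * (y * v[2] - z * v[1])
    ty = 2.0 * (z * v[0] - x * v[2])
    tz = 2.0 * (x * v[1] - y * v[0])
    out[0] = v[0] + w * tx + y * tz - z * ty
    out[1] = v[1] + w * ty + z * tx - x * tz
    out[2] = v[2] + w * tz + x * ty - y * tx


@njit(cache=True, inline="always")
def _rotate_about(v, wx, wy, wz, dt):
    """Rotate vector v in place by angle |w| dt about axis w."""
    ang = np.sqrt(wx * wx + wy * wy + wz * wz) * dt
    if ang < 1e-14:
        return
    inv = 1.0 / (ang / dt)
    ax = wx * inv
    ay = wy * inv
    az = wz * inv
    c = np.cos(ang)
    s = np.sin(ang)
    dot = ax * v[0] + ay * v[1] + az * v[2]
    cx = ay * v[2] - az * v[1]
    cy = az * v[0] - ax * v[2]
    cz = ax * v[1] - ay * v[0]
    v[0] = v[0] * c + cx * s + ax * dot * (1.0 - c)
    v[1] = v[1] * c + cy * s + ay * dot * (1.0 - c)
    v[2] = v[2] * c + cz * s + az * dot * (1.0 - c)


@njit(cache=True, inline="always")
def _quat_drift(q, wx, wy, wz, dt):
    """Advance quaternion by rotation (angular velocity w, duration dt)."""
    ang = np.sqrt(wx * wx + wy * wy + wz * wz) * dt
    if ang < 1e-14:
        return
    half = 0.5 * ang
    s = np.sin(half) / (ang / dt)
    dq = np.empty(4)
    dq[0] = np.cos(half)
    dq[1] = wx * s * dt / dt
    dq[1] = wx * s
    dq[2] = wy * s
    dq[3] = wz * s
    tmp = np.empty(4)
    _quat_mul(dq, q, tmp)
    norm = np.sqrt(tmp[0] ** 2 + tmp[1] ** 2 + tmp[2] ** 2 + tmp[3] ** 2)
    for k in range(4):
        q[k] = tmp[k] / norm


@njit(cache=True)
def bead_positions(sub_com, sub_quat, offsets, out):
    """Lab-frame bead positions of every subunit: out (n, 3, 3)."""
    n = sub_com.shape[0]
    v = np.empty(3)
    for s in range(n):
        for b in range(3):
            _quat_rotate(sub_quat[s], offsets[b], v)
            out[s, b, 0] = sub_com[s, 0] + v[0]
            out[s, b, 1] = sub_com[s, 1] + v[1]
            out[s, b, 2] = sub_com[s, 2] + v[2]


@njit(cache=True)
def assemble_positions(mem_pos, mem_nrm, sub_com, sub_quat, offsets,
                       pos_buf, nrm_buf, beads_buf):
    """Fill the flat particle arrays (membrane first, then beads)."""
    nm = mem_pos.shape[0]
    ns = sub_com.shape[0]
    pos_buf[:nm] = mem_pos
    nrm_buf[:] = 0.0
    nrm_buf[:nm] = mem_nrm
    bead_positions(sub_com, sub_quat, offsets, beads_buf)
    for s in range(ns):
        for b in range(3):
            idx = nm + 3 * s + b
            pos_buf[idx, 0] = beads_buf[s, b, 0]
            pos_buf[idx, 1] = beads_buf[s, b, 1]
            pos_buf[idx, 2] = beads_buf[s, b, 2]


@njit(cache=True)
def compute_forces(mem_pos, mem_nrm, sub_com, sub_quat, offsets,
                   active_lo, active_hi, rest, spring_k,
                   kind, subunit, alive,
                   mm_pairs, ad_pairs, rep_pairs, pair_counts,
                   eps_m, r_min, r_cut_m, zeta, mu, sin0,
                   eps_ad, sigma_ad, r_cut_ad, eps_rep,
                   pos_buf, nrm_buf, f_buf, t_buf, beads_buf, bead_f_buf,
                   mem_force, mem_torque, sub_force, sub_torque):
    """Evaluate all forces/torques; returns energy terms.

    Non-bonded terms come from the prebuilt Verlet pair lists (see
    :mod:`escrtsim.forces`).  Returns (E_membrane, E_adhesion,
    E_exclusion, E_spring).
    """
    nm = mem_pos.shape[0]
    ns = sub_com.shape[0]
    assemble_positions(mem_pos, mem_nrm, sub_com, sub_quat, offsets,
                       pos_buf, nrm_buf, beads_buf)
    e_mem, e_adh, e_exc = pair_nonbonded_forces(
        pos_buf, nrm_buf, kind, alive,
        mm_pairs, pair_counts[0], ad_pairs, pair_counts[1],
        rep_pairs, pair_counts[2],
        eps_m, r_min, r_cut_m, zeta, mu, sin0,
        eps_ad, sigma_ad, r_cut_ad, eps_rep,
        f_buf, t_buf)
    bead_f_buf[:] = 0.0
    e_spr = spring_forces(beads_buf, rest, spring_k, active_lo, active_hi, bead_f_buf)
    # collect per-bead non-bonded forces into the bead buffer
    for s in range(ns):
        for b in range(3):
            idx = nm + 3 * s + b
            bead_f_buf[s, b, 0] += f_buf[idx, 0]
            bead_f_buf[s, b, 1] += f_buf[idx, 1]
            bead_f_buf[s, b, 2] += f_buf[idx, 2]
    mem_force[:] = f_buf[:nm]
    mem_torque[:] = t_buf[:nm]
    # reduce bead forces to rigid-body force + torque about the COM
    for s in range(ns):
        fx = 0.0
        fy = 0.0
        fz = 0.0
        tx = 0.0
        ty = 0.0
        tz = 0.0
        for b in range(3):
            bfx = bead_f_buf[s, b, 0]
            bfy = bead_f_buf[s, b, 1]
            bfz = bead_f_buf[s, b, 2]
            fx += bfx
            fy += bfy
            fz += bfz
            rx = beads_buf[s, b, 0] - sub_com[s, 0]
            ry = beads_buf[s, b, 1] - sub_com[s, 1]
            rz = beads_buf[s, b, 2] - sub_com[s, 2]
            tx += ry * bfz - rz * bfy
            ty += rz * bfx - rx * bfz
            tz += rx * bfy - ry * bfx
        sub_force[s, 0] = fx
        sub_force[s, 1] = fy
        sub_force[s, 2] = fz
        sub_torque[s, 0] = tx
        sub_torque[s, 1] = ty
        sub_torque[s, 2] = tz
    return e_mem, e_adh, e_exc, e_spr


@njit(cache=True)
def langevin_step(mem_pos, mem_nrm, mem_vel, mem_ang,
                  sub_com, sub_quat, sub_vel, sub_ang,
                  offsets, active_lo, active_hi, rest, spring_k,
                  kind, subunit, alive,
                  mm_pairs, ad_pairs, rep_pairs, pair_counts,
                  eps_m, r_min, r_cut_m, zeta, mu, sin0,
                  eps_ad, sigma_ad, r_cut_ad, eps_rep,
                  dt, temperature, gamma_t, gamma_r, max_disp,
                  noise_mt, noise_mr, noise_st, noise_sr,
                  pos_buf, nrm_buf, f_buf, t_buf, beads_buf, bead_f_buf,
                  mem_force, mem_torque, sub_force, sub_torque):
    """One BAOAB Langevin step of the full system (dt = 0.01 tau).

    Forces in ``mem_force``/... must be valid on entry (as left by the
    previous step or an initial ``compute_forces`` call) and are updated
    in place.  Returns (E_mem, E_adh, E_exc, E_spring, max_displacement).
    Inactive subunits keep zero velocity and do not move.
    """
    nm = mem_pos.shape[0]
    ns = sub_com.shape[0]
    half = 0.5 * dt
    c1t = np.exp(-gamma_t * dt)
    c1r = np.exp(-gamma_r * dt)
    s_mt = np.sqrt((1.0 - c1t * c1t) * temperature / MEMBRANE_MASS)
    s_mr = np.sqrt((1.0 - c1r * c1r) * temperature / MEMBRANE_INERTIA)
    s_st = np.sqrt((1.0 - c1t * c1t) * temperature / SUBUNIT_MASS)
    s_sr = np.sqrt((1.0 - c1r * c1r) * temperature / SUBUNIT_INERTIA)
    max_d2 = 0.0

    # B (half kick) + A (half drift) + O + A
    for i in range(nm):
        for d in range(3):
            mem_vel[i, d] += half * mem_force[i, d] / MEMBRANE_MASS
            mem_ang[i, d] += half * mem_torque[i, d] / MEMBRANE_INERTIA
        x0 = mem_pos[i, 0]
        y0 = mem_pos[i, 1]
        z0 = mem_pos[i, 2]
        for d in range(3):
            mem_pos[i, d] += half * mem_vel[i, d]
        _rotate_about(mem_nrm[i], mem_ang[i, 0], mem_ang[i, 1], mem_ang[i, 2], half)
        for d in range(3):
            mem_vel[i, d] = c1t * mem_vel[i, d] + s_mt * noise_mt[i, d]
            mem_ang[i, d] = c1r * mem_ang[i, d] + s_mr * noise_mr[i, d]
        for d in range(3):
            mem_pos[i, d] += half * mem_vel[i, d]
        _rotate_about(mem_nrm[i], mem_ang[i, 0], mem_ang[i, 1], mem_ang[i, 2], half)
        nrm = np.sqrt(mem_nrm[i, 0] ** 2 + mem_nrm[i, 1] ** 2 + mem_nrm[i, 2] ** 2)
        for d in range(3):
            mem_nrm[i, d] /= nrm
        dx = mem_pos[i, 0] - x0
        dy = mem_pos[i, 1] - y0
        dz = mem_pos[i, 2] - z0
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > max_d2:
            max_d2 = d2
    for s in range(ns):
        if s < active_lo or s >= active_hi:
            continue
        for d in range(3):
            sub_vel[s, d] += half * sub_force[s, d] / SUBUNIT_MASS
            sub_ang[s, d] += half * sub_torque[s, d] / SUBUNIT_INERTIA
        x0 = sub_com[s, 0]
        y0 = sub_com[s, 1]
        z0 = sub_com[s, 2]
        for d in range(3):
            sub_com[s, d] += half * sub_vel[s, d]
        _quat_drift(sub_quat[s], sub_ang[s, 0], sub_ang[s, 1], sub_ang[s, 2], half)
        for d in range(3):
            sub_vel[s, d] = c1t * sub_vel[s, d] + s_st * noise_st[s, d]
            sub_ang[s, d] = c1r * sub_ang[s, d] + s_sr * noise_sr[s, d]
        for d in range(3):
            sub_com[s, d] += half * sub_vel[s, d]
        _quat_drift(sub_quat[s], sub_ang[s, 0], sub_ang[s, 1], sub_ang[s, 2], half)
        dx = sub_com[s, 0] - x0
        dy = sub_com[s, 1] - y0
        dz = sub_com[s, 2] - z0
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > max_d2:
            max_d2 = d2

    e_mem, e_adh, e_exc, e_spr = compute_forces(
        mem_pos, mem_nrm, sub_com, sub_quat, offsets,
        active_lo, active_hi, rest, spring_k,
        kind, subunit, alive,
        mm_pairs, ad_pairs, rep_pairs, pair_counts,
        eps_m, r_min, r_cut_m, zeta, mu, sin0,
        eps_ad, sigma_ad, r_cut_ad, eps_rep,
        pos_buf, nrm_buf, f_buf, t_buf, beads_buf, bead_f_buf,
        mem_force, mem_torque, sub_force, sub_torque)

    # final B (half kick)
    for i in range(nm):
        for d in range(3):
            mem_vel[i, d] += half * mem_force[i, d] / MEMBRANE_MASS
            mem_ang[i, d] += half * mem_torque[i, d] / MEMBRANE_INERTIA
    for s in range(active_lo, active_hi):
        for d in range(3):
            sub_vel[s, d] += half * sub_force[s, d] / SUBUNIT_MASS
            sub_ang[s, d] += half * sub_torque[s, d] / SUBUNIT_INERTIA

    return e_mem, e_adh, e_exc, e_spr, np.sqrt(max_d2)
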