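"""Cell-list force kernels (numba).

All short-range non-bonded interactions — the anisotropic membrane pair
potential, filament-membrane adhesion/exclusion, and filament
self-avoidance — are evaluated in a single pass over a cell list whose
cell edge is at least the largest cutoff, so no pair within range is
ever missed (exactness is verified against the NumPy references in the
tests).  Spring bonds are evaluated separately from the pair list of
consecutive active subunits.

Particle layout: membrane particles first (kind 0), then filament beads
subunit-major (kinds 1 = outer/adhesive, 2 = core, 3 = inner).
"""

from __future__ import annotations

import numpy as np
from numba import njit

KIND_MEMBRANE = 0
KIND_OUTER = 1
KIND_CORE = 2
KIND_INNER = 3

_WCA_FACTOR = 2.0 ** (1.0 / 6.0)


@njit(cache=True)
def _build_cell_list(pos, cell_size):
    n = pos.shape[0]
    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        lo[d] = pos[:, d].min() - 1e-9
        hi[d] = pos[:, d].max() + 1e-9
    ncell = np.empty(3, dtype=np.int64)
    for d in range(3):
        # cap the grid: with a runaway particle the bounding box can grow
        # without bound; larger-than-cutoff cells stay correct, just slower
        ncell[d] = min(128, max(1, int((hi[d] - lo[d]) / cell_size)))
    ntot = ncell[0] * ncell[1] * ncell[2]
    head = np.full(ntot, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        cx = min(ncell[0] - 1, int((pos[i, 0] - lo[0]) / (hi[0] - lo[0]) * ncell[0]))
        cy = min(ncell[1] - 1, int((pos[i, 1] - lo[1]) / (hi[1] - lo[1]) * ncell[1]))
        cz = min(ncell[2] - 1, int((pos[i, 2] - lo[2]) / (hi[2] - lo[2]) * ncell[2]))
        c = (cx * ncell[1] + cy) * ncell[2] + cz
        nxt[i] = head[c]
        head[c] = i
    return head, nxt, ncell

# NOTE: cells are sized (hi-lo)/ncell >= cell_size >= max cutoff, so a
# 27-cell stencil covers every in-range pair exactly once.


@njit(cache=True, fastmath=True, inline="always")
def _membrane_pair(dx, dy, dz, r, ni, nj, eps, r_min, r_cut, zeta, mu, sin0):
    """Returns (energy, du_dr, du_da, ci, cj); caller assembles vectors."""
    rx = dx / r
    ry = dy / r
    rz = dz / r
    ci = ni[0] * rx + ni[1] * ry + ni[2] * rz
    cj = nj[0] * rx + nj[1] * ry + nj[2] * rz
    ninj = ni[0] * nj[0] + ni[1] * nj[1] + ni[2] * nj[2]
    a = ninj - ci * cj + sin0 * ((nj[0] - ni[0]) * rx + (nj[1] - ni[1]) * ry
                                 + (nj[2] - ni[2]) * rz) - sin0 * sin0
    phi = 1.0 + mu * (a - 1.0)
    if r < r_min:
        sr2 = (r_min / r) ** 2
        u = eps * (sr2 * sr2 - 2.0 * sr2) + (1.0 - phi) * eps
        du_dr = eps * (-4.0 * sr2 * sr2 + 4.0 * sr2) / r
        du_da = -eps * mu
    else:
        psi = 0.5 * np.pi * (r - r_min) / (r_cut - r_min)
        c = np.cos(psi)
        # c^(2 zeta - 1) by repeated multiplication (2 zeta is an integer)
        n_pow = int(2.0 * zeta) - 1
        c2z1 = 1.0
        for _ in range(n_pow):
            c2z1 *= c
        u = -eps * phi * c2z1 * c
        du_dr = eps * phi * 2.0 * zeta * c2z1 * np.sin(psi) * 0.5 * np.pi / (r_cut - r_min)
        du_da = -eps * mu * c2z1 * c
    return u, du_dr, du_da, ci, cj


@njit(cache=True, fastmath=True, inline="always")
def _lj_ts(r, eps, sigma, r_cut):
    s6 = (sigma / r) ** 6
    sc6 = (sigma / r_cut) ** 6
    u = 4.0 * eps * (s6 * s6 - s6) - 4.0 * eps * (sc6 * sc6 - sc6)
    du = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
    return u, du


@njit(cache=True, fastmath=True, inline="always")
def _wca(r, eps, sigma):
    s6 = (sigma / r) ** 6
    u = 4.0 * eps * (s6 * s6 - s6) + eps
    du = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
    return u, du


@njit(cache=True, fastmath=True)
def nonbonded_forces(pos, normals, kind, subunit, alive,
                     eps_m, r_min, r_cut_m, zeta, mu, sin0,
                     eps_ad, sigma_ad, r_cut_ad, eps_rep,
                     forces, torques):
    """All non-bonded forces/torques in place; returns energy terms.

    ``normals`` has one row per particle (zero rows for filament beads).
    ``alive`` marks particles taking part (disassembled beads excluded).
    Returns (membrane energy, adhesion energy, exclusion energy).
    """
    n = pos.shape[0]
    forces[:] = 0.0
    torques[:] = 0.0
    wca_cut = _WCA_FACTOR * sigma_ad
    cutoff = max(r_cut_m, r_cut_ad)
    head, nxt, ncell = _build_cell_list(pos, cutoff)
    e_mem = 0.0
    e_adh = 0.0
    e_exc = 0.0
    for cx in range(ncell[0]):
        for cy in range(ncell[1]):
            for cz in range(ncell[2]):
                c = (cx * ncell[1] + cy) * ncell[2] + cz
                i = head[c]
                while i >= 0:
                    if not alive[i]:
                        i = nxt[i]
                        continue
                    for ox in range(-1, 2):
                        gx = cx + ox
                        if gx < 0 or gx >= ncell[0]:
                            continue
                        for oy in range(-1, 2):
                            gy = cy + oy
                            if gy < 0 or gy >= ncell[1]:
                                continue
                            for oz in range(-1, 2):
                                gz = cz + oz
                                if gz < 0 or gz >= ncell[2]:
                                    continue
                                g = (gx * ncell[1] + gy) * ncell[2] + gz
                                j = head[g]
                                while j >= 0:
                                    if j <= i or not alive[j]:
                                        j = nxt[j]
                                        continue
                                    dx = pos[j, 0] - pos[i, 0]
                                    dy = pos[j, 1] - pos[i, 1]
                                    dz = pos[j, 2] - pos[i, 2]
                                    r2 = dx * dx + dy * dy + dz * dz
                                    if r2 >= cutoff * cutoff:
                                        j = nxt[j]
                                        continue
                                    ki = kind[i]
                                    kj = kind[j]
                                    if ki == KIND_MEMBRANE and kj == KIND_MEMBRANE:
                                        r = np.sqrt(r2)
                                        if r < r_cut_m:
                                            e_mem += _mm_accumulate(
                                                i, j, dx, dy, dz, r, normals,
                                                eps_m, r_min, r_cut_m, zeta, mu,
                                                sin0, forces, torques)
                                    elif ki == KIND_MEMBRANE or kj == KIND_MEMBRANE:
                                        # membrane -- filament bead
                                        bead_kind = kj if ki == KIND_MEMBRANE else ki
                                        r = np.sqrt(r2)
                                        if bead_kind == KIND_OUTER:
                                            if r < r_cut_ad:
                                                u, du = _lj_ts(r, eps_ad, sigma_ad, r_cut_ad)
                                                e_adh += u
                                                _add_central(i, j, dx, dy, dz, r, du, forces)
                                        else:
                                            if r < wca_cut:
                                                u, du = _wca(r, eps_rep, sigma_ad)
                                                e_adh += u
                                                _add_central(i, j, dx, dy, dz, r, du, forces)
                                    else:
                                        # filament bead -- filament bead
                                        ds = subunit[i] - subunit[j]
                                        if ds < -1 or ds > 1:
                                            r = np.sqrt(r2)
                                            if r < wca_cut:
                                                u, du = _wca(r, eps_rep, sigma_ad)
                                                e_exc += u
                                                _add_central(i, j, dx, dy, dz, r, du, forces)
                                    j = nxt[j]
                    i = nxt[i]
    return e_mem, e_adh, e_exc


@njit(cache=True, fastmath=True, inline="always")
def _add_central(i, j, dx, dy, dz, r, du, forces):
    f = -du / r
    forces[j, 0] += f * dx
    forces[j, 1] += f * dy
    forces[j, 2] += f * dz
    forces[i, 0] -= f * dx
    forces[i, 1] -= f * dy
    forces[i, 2] -= f * dz


@njit(cache=True, fastmath=True, inline="always")
def _mm_accumulate(i, j, dx, dy, dz, r, normals,
                   eps, r_min, r_cut, zeta, mu, sin0, forces, torques):
    ni = normals[i]
    nj = normals[j]
    u, du_dr, du_da, ci, cj = _membrane_pair(dx, dy, dz, r, ni, nj,
                                             eps, r_min, r_cut, zeta, mu, sin0)
    rx = dx / r
    ry = dy / r
    rz = dz / r
    # da/dr_j = (-(cj*(ni - ci*rhat) + ci*(nj - cj*rhat)) + sin0*((nj-ni) - ((nj-ni).rhat) rhat)) / r
    dnx = nj[0] - ni[0]
    dny = nj[1] - ni[1]
    dnz = nj[2] - ni[2]
    dnr = dnx * rx + dny * ry + dnz * rz
    ax = (-(cj * (ni[0] - ci * rx) + ci * (nj[0] - cj * rx)) + sin0 * (dnx - dnr * rx)) / r
    ay = (-(cj * (ni[1] - ci * ry) + ci * (nj[1] - cj * ry)) + sin0 * (dny - dnr * ry)) / r
    az = (-(cj * (ni[2] - ci * rz) + ci * (nj[2] - cj * rz)) + sin0 * (dnz - dnr * rz)) / r
    gx = du_dr * rx + du_da * ax
    gy = du_dr * ry + du_da * ay
    gz = du_dr * rz + du_da * az
    forces[j, 0] -= gx
    forces[j, 1] -= gy
    forces[j, 2] -= gz
    forces[i, 0] += gx
    forces[i, 1] += gy
    forces[i, 2] += gz
    # torque on i: (du_da * da/dni) x ni  with da/dni = nj - cj*rhat - sin0*rhat
    hx = du_da * (nj[0] - cj * rx - sin0 * rx)
    hy = du_da * (nj[1] - cj * ry - sin0 * ry)
    hz = du_da * (nj[2] - cj * rz - sin0 * rz)
    torques[i, 0] += hy * ni[2] - hz * ni[1]
    torques[i, 1] += hz * ni[0] - hx * ni[2]
    torques[i, 2] += hx * ni[1] - hy * ni[0]
    # torque on j: da/dnj = ni - ci*rhat + sin0*rhat
    hx = du_da * (ni[0] - ci * rx + sin0 * rx)
    hy = du_da * (ni[1] - ci * ry + sin0 * ry)
    hz = du_da * (ni[2] - ci * rz + sin0 * rz)
    torques[j, 0] += hy * nj[2] - hz * nj[1]
    torques[j, 1] += hz * nj[0] - hx * nj[2]
    torques[j, 2] += hx * nj[1] - hy * nj[0]
    return u


@njit(cache=True, fastmath=True)
def spring_forces(bead_pos, rest, spring_k, lo, hi, forces):
    """Nine-spring bonds between consecutive active subunits [lo, hi).

    ``bead_pos`` is (n_subunits, 3, 3); ``rest`` is (n_subunits-1, 9).
    Adds forces in place into ``forces`` of the same shape; returns the
    spring energy.
    """
    energy = 0.0
    for p in range(lo, hi - 1):
        for ba in range(3):
            for bb in range(3):
                l0 = rest[p, 3 * ba + bb]
                dx = bead_pos[p, ba, 0] - bead_pos[p + 1, bb, 0]
                dy = bead_pos[p, ba, 1] - bead_pos[p + 1, bb, 1]
                dz = bead_pos[p, ba, 2] - bead_pos[p + 1, bb, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                delta = r - l0
                energy += 0.5 * spring_k * delta * delta
                f = -spring_k * delta / r
                forces[p, ba, 0] += f * dx
                forces[p, ba, 1] += f * dy
                forces[p, ba, 2] += f * dz
                forces[p + 1, bb, 0] -= f * dx
                forces[p + 1, bb, 1] -= f * dy
                forces[p + 1, bb, 2] -= f * dz
    return energy


@njit(cache=True)
def spring_tensions(bead_pos, rest, spring_k, lo, hi, tension_out):
    """Per-pair spring force projected on the local backbone tangent.

    For each consecutive active pair, sums the nine spring forces acting
    across the bond and projects them on the core-core unit vector;
    stretched bonds give positive tension.  Fills ``tension_out`` (one
    entry per pair in [lo, hi-1)) and returns the number of pairs.
    """
    npairs = 0
    for p in range(lo, hi - 1):
        tx = bead_pos[p + 1, 1, 0] - bead_pos[p, 1, 0]
        ty = bead_pos[p + 1, 1, 1] - bead_pos[p, 1, 1]
        tz = bead_pos[p + 1, 1, 2] - bead_pos[p, 1, 2]
        tn = np.sqrt(tx * tx + ty * ty + tz * tz)
        tx /= tn
        ty /= tn
        tz /= tn
        acc = 0.0
        for ba in range(3):
            for bb in range(3):
                l0 = rest[p, 3 * ba + bb]
                dx = bead_pos[p + 1, bb, 0] - bead_pos[p, ba, 0]
                dy = bead_pos[p + 1, bb, 1] - bead_pos[p, ba, 1]
                dz = bead_pos[p + 1, bb, 2] - bead_pos[p, ba, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                # force pulling the pair together along the bond, projected
                # on the backbone tangent; positive when stretched
                fmag = spring_k * (r - l0)
                acc += fmag * (dx * tx + dy * ty + dz * tz) / r
        tension_out[p - lo] = acc
        npairs += 1
    return npairs


# ---------------------------------------------------------------------------
# Verlet pair lists: the production driver rebuilds these only after
# particles have drifted a fraction of the skin, instead of scanning the
# cell grid every step.  Correctness: lists are rebuilt once the maximum
# displacement since the last build exceeds ``REBUILD_DISP``; a pair can
# then only be missed if a particle moves more than
# (VERLET_SKIN - 2*REBUILD_DISP) in a single step, far above the
# integrator's instability-abort threshold regime of healthy runs.
# ---------------------------------------------------------------------------

VERLET_SKIN = 0.8
REBUILD_DISP = 0.3


@njit(cache=True)
def build_pair_lists(pos, kind, subunit, alive,
                     r_mm, r_ad, r_rep,
                     mm_pairs, ad_pairs, rep_pairs):
    """Fill typed pair lists out to the Verlet radii; returns counts.

    ``mm_pairs``: membrane-membrane; ``ad_pairs``: membrane-filament
    bead (any bead kind; dispatched in the force loop); ``rep_pairs``:
    filament-filament non-bonded.  Returns (-1, -1, -1) if any capacity
    is exceeded (caller must grow the arrays and retry).
    """
    cutoff = max(r_mm, max(r_ad, r_rep))
    head, nxt, ncell = _build_cell_list(pos, cutoff)
    n_mm = 0
    n_ad = 0
    n_rep = 0
    r_mm2 = r_mm * r_mm
    r_ad2 = r_ad * r_ad
    r_rep2 = r_rep * r_rep
    for cx in range(ncell[0]):
        for cy in range(ncell[1]):
            for cz in range(ncell[2]):
                c = (cx * ncell[1] + cy) * ncell[2] + cz
                i = head[c]
                while i >= 0:
                    if not alive[i]:
                        i = nxt[i]
                        continue
                    for ox in range(-1, 2):
                        gx = cx + ox
                        if gx < 0 or gx >= ncell[0]:
                            continue
                        for oy in range(-1, 2):
                            gy = cy + oy
                            if gy < 0 or gy >= ncell[1]:
                                continue
                            for oz in range(-1, 2):
                                gz = cz + oz
                                if gz < 0 or gz >= ncell[2]:
                                    continue
                                g = (gx * ncell[1] + gy) * ncell[2] + gz
                                j = head[g]
                                while j >= 0:
                                    if j <= i or not alive[j]:
                                        j = nxt[j]
                                        continue
                                    dx = pos[j, 0] - pos[i, 0]
                                    dy = pos[j, 1] - pos[i, 1]
                                    dz = pos[j, 2] - pos[i, 2]
                                    r2 = dx * dx + dy * dy + dz * dz
                                    ki = kind[i]
                                    kj = kind[j]
                                    if ki == KIND_MEMBRANE and kj == KIND_MEMBRANE:
                                        if r2 < r_mm2:
                                            if n_mm >= mm_pairs.shape[0]:
                                                return -1, -1, -1
                                            mm_pairs[n_mm, 0] = i
                                            mm_pairs[n_mm, 1] = j
                                            n_mm += 1
                                    elif ki == KIND_MEMBRANE or kj == KIND_MEMBRANE:
                                        if r2 < r_ad2:
                                            if n_ad >= ad_pairs.shape[0]:
                                                return -1, -1, -1
                                            # store membrane first
                                            if ki == KIND_MEMBRANE:
                                                ad_pairs[n_ad, 0] = i
                                                ad_pairs[n_ad, 1] = j
                                            else:
                                                ad_pairs[n_ad, 0] = j
                                                ad_pairs[n_ad, 1] = i
                                            n_ad += 1
                                    else:
                                        ds = subunit[i] - subunit[j]
                                        if (ds < -1 or ds > 1) and r2 < r_rep2:
                                            if n_rep >= rep_pairs.shape[0]:
                                                return -1, -1, -1
                                            rep_pairs[n_rep, 0] = i
                                            rep_pairs[n_rep, 1] = j
                                            n_rep += 1
                                    j = nxt[j]
                    i = nxt[i]
    return n_mm, n_ad, n_rep


@njit(cache=True, fastmath=True)
def pair_nonbonded_forces(pos, normals, kind, alive,
                          mm_pairs, n_mm, ad_pairs, n_ad, rep_pairs, n_rep,
                          eps_m, r_min, r_cut_m, zeta, mu, sin0,
                          eps_ad, sigma_ad, r_cut_ad, eps_rep,
                          forces, torques):
    """Non-bonded forces from prebuilt pair lists (same output contract
    as :func:`nonbonded_forces`)."""
    forces[:] = 0.0
    torques[:] = 0.0
    wca_cut2 = (_WCA_FACTOR * sigma_ad) ** 2
    rc_m2 = r_cut_m * r_cut_m
    rc_ad2 = r_cut_ad * r_cut_ad
    e_mem = 0.0
    e_adh = 0.0
    e_exc = 0.0
    for p in range(n_mm):
        # membrane particles are never deactivated: no alive check needed
        i = mm_pairs[p, 0]
        j = mm_pairs[p, 1]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc_m2:
            r = np.sqrt(r2)
            e_mem += _mm_accumulate(i, j, dx, dy, dz, r, normals,
                                    eps_m, r_min, r_cut_m, zeta, mu, sin0,
                                    forces, torques)
    for p in range(n_ad):
        i = ad_pairs[p, 0]          # membrane particle
        j = ad_pairs[p, 1]          # filament bead
        if not (alive[i] and alive[j]):
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if kind[j] == KIND_OUTER:
            if r2 < rc_ad2:
                r = np.sqrt(r2)
                u, du = _lj_ts(r, eps_ad, sigma_ad, r_cut_ad)
                e_adh += u
                _add_central(i, j, dx, dy, dz, r, du, forces)
        else:
            if r2 < wca_cut2:
                r = np.sqrt(r2)
                u, du = _wca(r, eps_rep, sigma_ad)
                e_adh += u
                _add_central(i, j, dx, dy, dz, r, du, forces)
    for p in range(n_rep):
        i = rep_pairs[p, 0]
        j = rep_pairs[p, 1]
        if not (alive[i] and alive[j]):
            continue
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < wca_cut2:
            r = np.sqrt(r2)
            u, du = _wca(r, eps_rep, sigma_ad)
            e_exc += u
            _add_central(i, j, dx, dy, dz, r, du, forces)
    return e_mem, e_adh, e_exc


@njit(cache=True)
def max_displacement_since(pos, ref, alive):
    m = 0.0
    for i in range(pos.shape[0]):
        if not alive[i]:
            continue
        dx = pos[i, 0] - ref[i, 0]
        dy = pos[i, 1] - ref[i, 1]
        dz = pos[i, 2] - ref[i, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return np.sqrt(m)
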