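"""Particle types, filament geometry, and the force fields.

The filament is a chain of rigid three-bead subunits (outer/adhesive,
core, inner) joined by nine harmonic springs per consecutive pair; the
spring rest lengths encode the target helix geometry.  The membrane is a
one-particle-thick fluid sheet of orientation-carrying particles; the
vesicle it closes into represents the archaeal cell.

This module holds the geometry builders and straightforward NumPy
reference implementations of every pair interaction.  The production
simulation loop uses the numba kernels in :mod:`escrtsim.forces`, which
are validated against these references in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import AdhesionParams, FilamentParams, HelixSpec, MembraneParams

# bead indices within a subunit
OUTER, CORE, INNER = 0, 1, 2


@dataclass
class Filament:
    """State of the filament: per-subunit bead positions and activity.

    ``beads`` has shape (n_subunits, 3, 3): subunit, bead (outer, core,
    inner), coordinate.  ``active`` marks subunits not yet disassembled;
    active subunits always form one contiguous index range because
    disassembly proceeds from both ends.
    """

    beads: np.ndarray
    active: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float)
        if self.beads.ndim != 3 or self.beads.shape[1:] != (3, 3):
            raise ValueError("beads must have shape (n, 3, 3)")
        if self.active is None:
            self.active = np.ones(len(self.beads), dtype=bool)
        self.active = np.asarray(self.active, dtype=bool)

    @property
    def n_subunits(self) -> int:
        return int(self.beads.shape[0])

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    @property
    def active_range(self) -> tuple[int, int]:
        """Half-open [lo, hi) index range of active subunits."""
        idx = np.flatnonzero(self.active)
        if idx.size == 0:
            return (0, 0)
        lo, hi = int(idx[0]), int(idx[-1]) + 1
        if hi - lo != idx.size:
            raise ValueError("active subunits are not contiguous")
        return lo, hi

    def core_positions(self, active_only: bool = True) -> np.ndarray:
        if active_only:
            return self.beads[self.active, CORE]
        return self.beads[:, CORE]


@dataclass
class Membrane:
    """Membrane particle set: positions and outward unit normals."""

    pos: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.pos.shape != self.normals.shape or self.pos.ndim != 2:
            raise ValueError("pos and normals must both be (n, 3)")

    @property
    def n_particles(self) -> int:
        return int(self.pos.shape[0])


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

def helix_points(spec: HelixSpec, radial_offset: float = 0.0) -> np.ndarray:
    """Points on an ideal helix, displaced radially by ``radial_offset``."""
    n = spec.n_subunits
    t = np.arange(n) * (2.0 * np.pi * spec.n_turns / n)
    r = spec.radius + radial_offset
    z = spec.axial_width * (t / (2.0 * np.pi * spec.n_turns)) - spec.axial_width / 2.0
    return np.column_stack([
        r * np.cos(t),
        spec.handedness * r * np.sin(t),
        z,
    ])


def build_helix(spec: HelixSpec, filament_params: FilamentParams | None = None) -> Filament:
    """Build an ideal helical filament of rigid three-bead subunits.

    Core beads lie on the helix of ``spec``; outer beads are displaced
    radially outward (toward the membrane) and inner beads inward by one
    bead separation.  Subunits are equally spaced by arc length.

    Raises
    ------
    ValueError
        If the inter-subunit spacing falls below one bead diameter
        (subunits would overlap).
    """
    fp = filament_params or FilamentParams()
    if spec.arc_step < fp.bead_diameter:
        raise ValueError(
            f"subunit spacing {spec.arc_step:.3f} sigma is below one bead "
            f"diameter ({fp.bead_diameter} sigma): subunits overlap"
        )
    core = helix_points(spec)
    outer = helix_points(spec, radial_offset=fp.bead_sep)
    inner = helix_points(spec, radial_offset=-fp.bead_sep)
    beads = np.stack([outer, core, inner], axis=1)
    return Filament(beads=beads)


def target_spec(initial: HelixSpec, target_ratio: float,
                filament_params: FilamentParams | None = None) -> HelixSpec:
    """Constricted target geometry at radius ``target_ratio * R_cell``.

    The filament is inextensible: the arc length per subunit of the
    target helix equals that of the initial helix.  The target coil turns
    stack with an axial pitch of ``target_pitch`` per turn so that
    successive turns do not interpenetrate.
    """
    fp = filament_params or FilamentParams()
    r_t = target_ratio * initial.radius
    if r_t <= 0:
        raise ValueError("target radius must be positive")
    total_arc = initial.arc_step * initial.n_subunits
    turn_len = np.hypot(2.0 * np.pi * r_t, fp.target_pitch)
    n_turns_t = total_arc / turn_len
    return HelixSpec(
        radius=r_t,
        n_turns=float(n_turns_t),
        n_subunits=initial.n_subunits,
        axial_width=float(n_turns_t * fp.target_pitch),
        handedness=initial.handedness,
    )


def rest_lengths_for_geometry(spec: HelixSpec,
                              filament_params: FilamentParams | None = None) -> np.ndarray:
    """Nine spring rest lengths encoding the helix geometry of ``spec``.

    Returns the 3x3 flattened array of bead-bead distances between two
    consecutive subunits on the ideal helix, ordered (outer, core,
    inner) x (outer, core, inner).  By helical symmetry the same nine
    lengths apply to every consecutive pair.
    """
    fil = build_helix(spec, filament_params)
    a, b = fil.beads[0], fil.beads[1]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return d.reshape(9).copy()


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform distribution of ``n`` points on a sphere."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return radius * pts


def build_vesicle(radius: float, spacing: float = 0.91,
                  membrane_params: MembraneParams | None = None) -> Membrane:
    """Spherical vesicle of membrane particles with outward normals.

    The particle count is set by the area budget 4 pi R^2 / spacing^2 on
    a Fibonacci lattice, which is quasi-uniform.  A warning is emitted if
    ``spacing`` is far from the fluid-phase equilibrium spacing of the
    pair potential (the sheet would be pre-strained).
    """
    if radius < 8.0:
        raise ValueError("vesicle radius must be at least 8 sigma")
    mp = membrane_params or MembraneParams()
    if not (0.88 * mp.equilibrium_spacing <= spacing <= 1.25 * mp.equilibrium_spacing):
        import warnings
        warnings.warn(
            f"spacing {spacing} sigma is far from the fluid-phase equilibrium "
            f"spacing {mp.equilibrium_spacing:.2f} sigma; the sheet will "
            "shrink or tear as it relaxes",
            stacklevel=2,
        )
    n = int(round(4.0 * np.pi * radius * radius / (spacing * spacing)))
    pos = fibonacci_sphere(n, radius)
    normals = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return Membrane(pos=pos, normals=normals)


# ---------------------------------------------------------------------------
# filament springs
# ---------------------------------------------------------------------------

def filament_spring_forces(filament: Filament, rest_lengths: np.ndarray,
                           spring_k: float = 600.0) -> tuple[np.ndarray, float]:
    """Forces and energy of the nine-spring bonds between active pairs.

    ``rest_lengths`` is (n_pairs, 9) with n_pairs = n_subunits - 1, in
    (outer, core, inner) x (outer, core, inner) order; rows for inactive
    pairs are ignored.  Energy is sum of (K/2)(l - l0)^2; forces are the
    exact negative gradients, so the net force and net torque on the
    filament vanish.
    """
    beads = filament.beads
    n = filament.n_subunits
    rest = np.asarray(rest_lengths, dtype=float)
    if rest.shape != (n - 1, 9):
        raise ValueError(f"rest_lengths must have shape ({n - 1}, 9)")
    lo, hi = filament.active_range
    forces = np.zeros_like(beads)
    energy = 0.0
    if hi - lo < 2:
        return forces, energy
    a = beads[lo:hi - 1]          # (p, 3, 3)
    b = beads[lo + 1:hi]
    dvec = a[:, :, None, :] - b[:, None, :, :]      # (p, 3, 3, 3)
    dist = np.linalg.norm(dvec, axis=-1)
    l0 = rest[lo:hi - 1].reshape(-1, 3, 3)
    if np.any(dist < 1e-12):
        raise FloatingPointError("coincident bonded beads")
    delta = dist - l0
    energy = float(0.5 * spring_k * np.sum(delta * delta))
    fmag = -spring_k * delta / dist                  # dU/dl per unit vector
    pair_f = fmag[..., None] * dvec                  # force on bead of subunit i
    forces[lo:hi - 1] += pair_f.sum(axis=2)
    forces[lo + 1:hi] -= pair_f.sum(axis=1)
    return forces, energy


# ---------------------------------------------------------------------------
# membrane pair potential (single-pair reference implementation)
# ---------------------------------------------------------------------------

def membrane_pair_interaction(pos_i: np.ndarray, n_i: np.ndarray,
                              pos_j: np.ndarray, n_j: np.ndarray,
                              params: MembraneParams):
    """Energy, forces and torques of one membrane particle pair.

    The potential has a soft repulsive core for r < r_min and, out to
    r_cut, an attraction of depth epsilon modulated by the mutual
    orientation factor

        phi = 1 + mu * (a - 1),
        a   = n_i.n_j - (n_i.rhat)(n_j.rhat)
              + sin(theta0) * (n_j - n_i).rhat - sin(theta0)^2,

    which is maximal (a = 1) for coplanar-aligned normals perpendicular
    to the separation.  Forces and torques are the exact gradients;
    Newton's third law holds pairwise.

    Returns ``(energy, f_i, f_j, t_i, t_j)``; beyond the cutoff all are
    zero.
    """
    p = params
    rvec = np.asarray(pos_j, float) - np.asarray(pos_i, float)
    r = float(np.linalg.norm(rvec))
    if r < 1e-10:
        raise FloatingPointError("overlapping membrane particles")
    zero = np.zeros(3)
    if r >= p.r_cut:
        return 0.0, zero, zero.copy(), zero.copy(), zero.copy()
    rhat = rvec / r
    ni = np.asarray(n_i, float)
    nj = np.asarray(n_j, float)
    ci = float(ni @ rhat)
    cj = float(nj @ rhat)
    s0 = np.sin(p.theta0)
    a = float(ni @ nj) - ci * cj + s0 * float((nj - ni) @ rhat) - s0 * s0
    phi = 1.0 + p.mu * (a - 1.0)

    # da/dn and da/dr_j (through rhat)
    da_dni = nj - cj * rhat - s0 * rhat
    da_dnj = ni - ci * rhat + s0 * rhat
    da_drj = (-(cj * (ni - ci * rhat) + ci * (nj - cj * rhat))
              + s0 * ((nj - ni) - float((nj - ni) @ rhat) * rhat)) / r

    if r < p.r_min:
        sr2 = (p.r_min / r) ** 2
        u_rep = p.epsilon * (sr2 * sr2 - 2.0 * sr2)
        energy = u_rep + (1.0 - phi) * p.epsilon
        du_dr = p.epsilon * (-4.0 * sr2 * sr2 + 4.0 * sr2) / r
        du_da = -p.epsilon * p.mu
    else:
        psi = (np.pi / 2.0) * (r - p.r_min) / (p.r_cut - p.r_min)
        c = np.cos(psi)
        energy = -p.epsilon * phi * c ** (2.0 * p.zeta)
        du_dr = (p.epsilon * phi * 2.0 * p.zeta * c ** (2.0 * p.zeta - 1.0)
                 * np.sin(psi) * (np.pi / 2.0) / (p.r_cut - p.r_min))
        du_da = -p.epsilon * p.mu * c ** (2.0 * p.zeta)

    grad_j = du_dr * rhat + du_da * da_drj
    f_j = -grad_j
    f_i = -f_j
    g_i = du_da * da_dni
    g_j = du_da * da_dnj
    t_i = np.cross(g_i, ni)
    t_j = np.cross(g_j, nj)
    return float(energy), f_i, f_j, t_i, t_j


# ---------------------------------------------------------------------------
# adhesion (filament bead -- membrane particle)
# ---------------------------------------------------------------------------

def lj_trunc_shift(r: float, eps: float, sigma: float, r_cut: float) -> tuple[float, float]:
    """Truncated-shifted 12-6 energy and dU/dr (zero beyond cutoff)."""
    if r >= r_cut:
        return 0.0, 0.0
    s6 = (sigma / r) ** 6
    sc6 = (sigma / r_cut) ** 6
    u = 4.0 * eps * (s6 * s6 - s6) - 4.0 * eps * (sc6 * sc6 - sc6)
    du = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
    return u, du


def wca(r: float, eps: float, sigma: float) -> tuple[float, float]:
    """Purely repulsive 12-6 (cut and shifted at its minimum)."""
    r_cut = 2.0 ** (1.0 / 6.0) * sigma
    if r >= r_cut:
        return 0.0, 0.0
    s6 = (sigma / r) ** 6
    u = 4.0 * eps * (s6 * s6 - s6) + eps
    du = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
    return u, du


def adhesion_pair(r: float, bead_kind: int, params: AdhesionParams) -> tuple[float, float]:
    """Energy and dU/dr between a filament bead and a membrane particle.

    Outer beads (bead_kind 0) attract; core and inner beads are purely
    repulsive volume exclusion.
    """
    if bead_kind == OUTER:
        return lj_trunc_shift(r, params.epsilon_ad, params.sigma_ad, params.r_cut_ad)
    return wca(r, params.epsilon_rep, params.sigma_ad)


def adhesion_forces(filament: Filament, membrane: Membrane,
                    params: AdhesionParams) -> tuple[np.ndarray, np.ndarray, float]:
    """All filament-membrane forces (reference implementation, O(N*M)).

    Returns (force on each filament bead (n,3,3), force on each membrane
    particle (m,3), energy).  Suitable for tests and small systems; the
    simulation loop uses the cell-list kernel instead.
    """
    fil_f = np.zeros_like(filament.beads)
    mem_f = np.zeros_like(membrane.pos)
    energy = 0.0
    active = np.flatnonzero(filament.active)
    for s in active:
        for b in range(3):
            dvec = membrane.pos - filament.beads[s, b]   # toward membrane
            dist = np.linalg.norm(dvec, axis=1)
            cut = params.r_cut_ad if b == OUTER else 2.0 ** (1 / 6) * params.sigma_ad
            for m in np.flatnonzero(dist < cut):
                u, du = adhesion_pair(float(dist[m]), b, params)
                energy += u
                f_on_mem = -du * dvec[m] / dist[m]
                mem_f[m] += f_on_mem
                fil_f[s, b] -= f_on_mem
    return fil_f, mem_f, energy
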