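"""Simulation state, Langevin driver, constriction protocols, disassembly.

A division run proceeds in phases:

1. relaxation — the filament ring, built just inside the vesicle with
   its rest geometry at the cell radius, equilibrates while adsorbed;
2. constriction — bond rest lengths switch, pair by pair or all at
   once, to the tight target-radius set (instantaneous / sequential /
   randomized protocols);
3. disassembly — once every bond has transitioned, one subunit is
   removed from each filament end every ``m_dis`` steps;
4. grace — after full disassembly the membrane is given time to finish
   (or fail) scission before the run is declared over.

Division is detected from the connected components of the membrane
adjacency graph.  Runs are fully reproducible given (config, schedule).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import forces as force_kernels
from . import integrate, observables
from .forces import KIND_CORE, KIND_INNER, KIND_MEMBRANE, KIND_OUTER
from .model import CORE, Filament, Membrane, build_helix, build_vesicle, \
    rest_lengths_for_geometry, target_spec
from .params import HelixSpec, ProtocolSchedule, SimConfig


class InstabilityError(RuntimeError):
    """A particle moved farther than the stability threshold in one step."""


@dataclass
class SimulationState:
    """Complete mutable state of a running simulation."""

    time: float
    step: int
    mem_pos: np.ndarray
    mem_nrm: np.ndarray
    mem_vel: np.ndarray
    mem_ang: np.ndarray
    sub_com: np.ndarray
    sub_quat: np.ndarray
    sub_vel: np.ndarray
    sub_ang: np.ndarray
    active: np.ndarray              # (n_subunits,) bool
    rest: np.ndarray                # (n_pairs, 9) current rest lengths
    transitioned: np.ndarray        # (n_pairs,) bool, monotone
    removed_side: np.ndarray        # (n_subunits,) -1 none, 0 left, 1 right
    removal_pos: np.ndarray         # (n_subunits, 3) core position at removal
    protocol_steps: int = 0         # steps taken in the constriction phase
    disassembly_steps: int = 0
    fully_disassembled: bool = False
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    @property
    def n_subunits(self) -> int:
        return int(self.active.shape[0])

    @property
    def active_range(self) -> tuple[int, int]:
        idx = np.flatnonzero(self.active)
        if idx.size == 0:
            return (0, 0)
        return int(idx[0]), int(idx[-1]) + 1

    @property
    def n_removed_left(self) -> int:
        return int(np.sum(self.removed_side == 0))

    @property
    def n_removed_right(self) -> int:
        return int(np.sum(self.removed_side == 1))

    def filament(self) -> Filament:
        beads = np.empty((self.n_subunits, 3, 3))
        integrate.bead_positions(self.sub_com, self.sub_quat,
                                 _bead_offsets(), beads)
        return Filament(beads=beads, active=self.active.copy())

    def membrane(self) -> Membrane:
        return Membrane(pos=self.mem_pos.copy(), normals=self.mem_nrm.copy())


def _bead_offsets(bead_sep: float = 1.0) -> np.ndarray:
    """Body-frame bead offsets (outer, core, inner) about the COM."""
    return np.array([[bead_sep, 0.0, 0.0],
                     [0.0, 0.0, 0.0],
                     [-bead_sep, 0.0, 0.0]])


def _quat_from_x_axis(x_dirs: np.ndarray) -> np.ndarray:
    """Minimal-rotation quaternions mapping e_x onto each row of x_dirs."""
    n = x_dirs.shape[0]
    quats = np.empty((n, 4))
    ex = np.array([1.0, 0.0, 0.0])
    for i in range(n):
        v = x_dirs[i] / np.linalg.norm(x_dirs[i])
        c = float(ex @ v)
        if c > 1.0 - 1e-12:
            quats[i] = (1.0, 0.0, 0.0, 0.0)
            continue
        if c < -1.0 + 1e-12:
            quats[i] = (0.0, 0.0, 0.0, 1.0)  # 180 deg about z
            continue
        axis = np.cross(ex, v)
        axis /= np.linalg.norm(axis)
        half = 0.5 * np.arccos(c)
        quats[i] = (np.cos(half), *(np.sin(half) * axis))
    return quats


class Simulation:
    """Langevin simulation of one filament-in-vesicle system."""

    def __init__(self, config: SimConfig, schedule: ProtocolSchedule):
        self.config = config
        self.schedule = schedule
        cfg = config
        self.rng = np.random.default_rng(schedule.rng_seed)

        membrane = build_vesicle(cfg.vesicle_radius, cfg.vesicle_spacing,
                                 cfg.membrane)
        # Place the ring just inside the membrane.  The outer beads sit at
        # least one LJ contact distance inside the vesicle wall even at the
        # helix ends (the helix is cylindrical, the wall spherical), and the
        # angular span grows so the arc length per subunit matches the rest
        # geometry: the filament starts bent inward but unstretched.
        contact = 2.0 ** (1.0 / 6.0) * cfg.adhesion.sigma_ad
        w = cfg.helix.axial_width
        r_outer = np.sqrt((cfg.vesicle_radius - contact) ** 2 - (w / 2.0) ** 2)
        r_core = r_outer - cfg.filament.bead_sep
        place = dataclasses.replace(
            cfg.helix, radius=r_core,
            n_turns=cfg.helix.n_turns * cfg.helix.radius / r_core)
        filament = build_helix(place, cfg.filament)

        ns = filament.n_subunits
        nm = membrane.n_particles
        self.n_mem = nm
        self.n_sub = ns
        self.offsets = _bead_offsets(cfg.filament.bead_sep)

        core = filament.beads[:, CORE]
        radial = filament.beads[:, 0] - core   # outer - core
        state = SimulationState(
            time=0.0, step=0,
            mem_pos=membrane.pos.copy(), mem_nrm=membrane.normals.copy(),
            mem_vel=np.zeros((nm, 3)), mem_ang=np.zeros((nm, 3)),
            sub_com=core.copy(), sub_quat=_quat_from_x_axis(radial),
            sub_vel=np.zeros((ns, 3)), sub_ang=np.zeros((ns, 3)),
            active=np.ones(ns, dtype=bool),
            rest=np.tile(rest_lengths_for_geometry(cfg.helix, cfg.filament),
                         (ns - 1, 1)),
            transitioned=np.zeros(ns - 1, dtype=bool),
            removed_side=np.full(ns, -1, dtype=np.int64),
            removal_pos=np.zeros((ns, 3)),
            rng=self.rng,
        )
        self.state = state
        self.target_rest = rest_lengths_for_geometry(
            target_spec(cfg.helix, schedule.target_ratio, cfg.filament),
            cfg.filament)
        self._transition_order = self._make_order()
        self._n_transitioned = 0

        # static particle metadata for the force kernel
        n_tot = nm + 3 * ns
        self.kind = np.empty(n_tot, dtype=np.int64)
        self.kind[:nm] = KIND_MEMBRANE
        for s in range(ns):
            self.kind[nm + 3 * s + 0] = KIND_OUTER
            self.kind[nm + 3 * s + 1] = KIND_CORE
            self.kind[nm + 3 * s + 2] = KIND_INNER
        self.subunit = np.full(n_tot, -1, dtype=np.int64)
        for s in range(ns):
            self.subunit[nm + 3 * s:nm + 3 * s + 3] = s
        self.alive = np.ones(n_tot, dtype=np.bool_)

        # work buffers
        self._pos_buf = np.empty((n_tot, 3))
        self._nrm_buf = np.zeros((n_tot, 3))
        self._f_buf = np.zeros((n_tot, 3))
        self._t_buf = np.zeros((n_tot, 3))
        self._beads_buf = np.empty((ns, 3, 3))
        self._bead_f_buf = np.zeros((ns, 3, 3))
        self.mem_force = np.zeros((nm, 3))
        self.mem_torque = np.zeros((nm, 3))
        self.sub_force = np.zeros((ns, 3))
        self.sub_torque = np.zeros((ns, 3))

        # Verlet pair lists, rebuilt when particles drift a fraction of
        # the skin (uniform translations do not invalidate them)
        wca_cut = 2.0 ** (1.0 / 6.0) * cfg.adhesion.sigma_ad
        self._r_verlet_mm = cfg.membrane.r_cut + force_kernels.VERLET_SKIN
        self._r_verlet_ad = (max(cfg.adhesion.r_cut_ad, wca_cut)
                             + force_kernels.VERLET_SKIN)
        self._r_verlet_rep = wca_cut + force_kernels.VERLET_SKIN
        self._mm_pairs = np.empty((48 * n_tot, 2), dtype=np.int64)
        self._ad_pairs = np.empty((24 * n_tot, 2), dtype=np.int64)
        self._rep_pairs = np.empty((24 * n_tot, 2), dtype=np.int64)
        self._pair_counts = np.zeros(3, dtype=np.int64)
        self._pair_ref = np.zeros((n_tot, 3))
        self._rebuild_pairs()
        self.energies = self._compute_forces()

    def _rebuild_pairs(self) -> None:
        integrate.assemble_positions(
            self.state.mem_pos, self.state.mem_nrm, self.state.sub_com,
            self.state.sub_quat, self.offsets,
            self._pos_buf, self._nrm_buf, self._beads_buf)
        while True:
            counts = force_kernels.build_pair_lists(
                self._pos_buf, self.kind, self.subunit, self.alive,
                self._r_verlet_mm, self._r_verlet_ad, self._r_verlet_rep,
                self._mm_pairs, self._ad_pairs, self._rep_pairs)
            if counts[0] >= 0:
                break
            self._mm_pairs = np.empty((2 * self._mm_pairs.shape[0], 2),
                                      dtype=np.int64)
            self._ad_pairs = np.empty((2 * self._ad_pairs.shape[0], 2),
                                      dtype=np.int64)
            self._rep_pairs = np.empty((2 * self._rep_pairs.shape[0], 2),
                                       dtype=np.int64)
        self._pair_counts[:] = counts
        self._pair_ref[:] = self._pos_buf

    # -- protocol bookkeeping ------------------------------------------------

    def _make_order(self) -> np.ndarray:
        n_pairs = self.n_sub - 1
        if self.schedule.mode == "randomized":
            order_rng = np.random.default_rng(
                np.random.SeedSequence([self.schedule.rng_seed, 1]))
            return order_rng.permutation(n_pairs)
        return np.arange(n_pairs)

    @property
    def n_transitioned(self) -> int:
        return self._n_transitioned

    def apply_protocol(self) -> int:
        """Advance the constriction protocol by one step's worth of switches.

        Returns the number of pairs that transitioned during this call.
        Instantaneous mode switches every pair on the first protocol step;
        the other modes switch one pair every ``n_curv`` steps, in index
        order (sequential) or seeded random order (randomized).  A no-op
        once every pair has transitioned.
        """
        st = self.state
        st.protocol_steps += 1
        n_pairs = st.transitioned.shape[0]
        if self._n_transitioned >= n_pairs:
            return 0
        if self.schedule.mode == "instantaneous":
            switched = n_pairs - self._n_transitioned
            st.rest[:] = self.target_rest
            st.transitioned[:] = True
            self._n_transitioned = n_pairs
            return switched
        if st.protocol_steps % self.schedule.n_curv != 0:
            return 0
        pair = int(self._transition_order[self._n_transitioned])
        st.rest[pair] = self.target_rest
        st.transitioned[pair] = True
        self._n_transitioned += 1
        return 1

    @property
    def all_transitioned(self) -> bool:
        return self._n_transitioned >= self.state.transitioned.shape[0]

    # -- disassembly ---------------------------------------------------------

    def disassemble_step(self) -> int:
        """Advance disassembly by one step; returns subunits removed (0 or 2).

        Every ``m_dis`` steps one subunit is deactivated at each filament
        end (its springs, adhesion and excluded volume vanish).  When
        fewer than three subunits remain active the filament is marked
        fully disassembled.
        """
        st = self.state
        if self.schedule.m_dis == 0 or st.fully_disassembled:
            return 0
        st.disassembly_steps += 1
        if st.disassembly_steps % self.schedule.m_dis != 0:
            return 0
        removed = 0
        beads = self._beads_buf
        lo, hi = st.active_range
        if hi - lo >= 2:
            for side, idx in ((0, lo), (1, hi - 1)):
                st.active[idx] = False
                st.removed_side[idx] = side
                st.removal_pos[idx] = beads[idx, CORE]
                self.alive[self.n_mem + 3 * idx:self.n_mem + 3 * idx + 3] = False
                st.sub_vel[idx] = 0.0
                st.sub_ang[idx] = 0.0
                removed += 1
        if st.active.sum() < 3:
            lo, hi = st.active_range
            for idx in range(lo, hi):
                if st.active[idx]:
                    side = 0 if (idx - lo) <= (hi - 1 - idx) else 1
                    st.active[idx] = False
                    st.removed_side[idx] = side
                    st.removal_pos[idx] = beads[idx, CORE]
                    self.alive[self.n_mem + 3 * idx:self.n_mem + 3 * idx + 3] = False
            st.fully_disassembled = True
        return removed

    # -- integration ---------------------------------------------------------

    def _force_args(self):
        cfg = self.config
        mp, ap = cfg.membrane, cfg.adhesion
        lo, hi = self.state.active_range
        return (self.state.mem_pos, self.state.mem_nrm,
                self.state.sub_com, self.state.sub_quat, self.offsets,
                lo, hi, self.state.rest, cfg.filament.spring_k,
                self.kind, self.subunit, self.alive,
                self._mm_pairs, self._ad_pairs, self._rep_pairs,
                self._pair_counts,
                mp.epsilon, mp.r_min, mp.r_cut, mp.zeta, mp.mu,
                np.sin(mp.theta0),
                ap.epsilon_ad, ap.sigma_ad, ap.r_cut_ad, ap.epsilon_rep,
                self._pos_buf, self._nrm_buf, self._f_buf, self._t_buf,
                self._beads_buf, self._bead_f_buf,
                self.mem_force, self.mem_torque,
                self.sub_force, self.sub_torque)

    def _compute_forces(self):
        return integrate.compute_forces(*self._force_args())

    def step(self) -> None:
        """One Langevin step (0.01 tau) of the whole system."""
        ip = self.config.integrator
        st = self.state
        if force_kernels.max_displacement_since(
                self._pos_buf, self._pair_ref,
                self.alive) > force_kernels.REBUILD_DISP:
            self._rebuild_pairs()
        noise_mt = self.rng.standard_normal((self.n_mem, 3))
        noise_mr = self.rng.standard_normal((self.n_mem, 3))
        noise_st = self.rng.standard_normal((self.n_sub, 3))
        noise_sr = self.rng.standard_normal((self.n_sub, 3))
        args = self._force_args()
        out = integrate.langevin_step(
            *args[:2], st.mem_vel, st.mem_ang,
            *args[2:4], st.sub_vel, st.sub_ang,
            *args[4:9],
            *args[9:12],
            *args[12:16],
            *args[16:26],
            ip.dt, ip.temperature, ip.gamma_t, ip.gamma_r, ip.max_disp,
            noise_mt, noise_mr, noise_st, noise_sr,
            *args[26:])
        self.energies = out[:4]
        max_disp = out[4]
        if not np.isfinite(max_disp) or max_disp > ip.max_disp:
            raise InstabilityError(
                f"displacement {max_disp:.3f} sigma in one step at "
                f"t={st.time:.2f} tau; check forces or reduce the timestep")
        st.step += 1
        st.time = st.step * ip.dt

    def recenter(self) -> None:
        """Shift the frame so the membrane COM sits at the origin.

        A uniform translation of every coordinate: forces and the sampled
        ensemble are unchanged, but the midzone slab (fixed at the box
        center) stays centered on the cell.
        """
        shift = self.state.mem_pos.mean(axis=0)
        self.state.mem_pos -= shift
        self.state.sub_com -= shift
        self.state.removal_pos[self.state.removed_side >= 0] -= shift
        # keep the pair-list reference frame consistent (pair validity is
        # translation invariant, the drift monitor is not)
        self._pos_buf -= shift
        self._pair_ref -= shift

    def run_steps(self, n_steps: int, protocol: bool = False,
                  disassembly: bool = False) -> None:
        for _ in range(n_steps):
            if protocol:
                self.apply_protocol()
            if disassembly and self.all_transitioned:
                self.disassemble_step()
            self.step()


def measured_temperature(sim: Simulation) -> float:
    """Kinetic temperature of all translational degrees of freedom."""
    st = sim.state
    lo, hi = st.active_range
    ke = (0.5 * integrate.MEMBRANE_MASS * np.sum(st.mem_vel ** 2)
          + 0.5 * integrate.SUBUNIT_MASS * np.sum(st.sub_vel[lo:hi] ** 2))
    ndof = 3 * (st.mem_pos.shape[0] + max(0, hi - lo))
    return float(2.0 * ke / ndof)


# ---------------------------------------------------------------------------
# top-level division driver
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryFrame:
    time: float
    mem_pos: np.ndarray
    mem_nrm: np.ndarray
    fil_beads: np.ndarray
    fil_active: np.ndarray


@dataclass
class DivisionRun:
    """Result of :func:`run_division`: observables, frames and outcome."""

    outcome: "observables.DivisionOutcome"
    table: "object"                 # pandas DataFrame of per-interval observables
    frames: list[TrajectoryFrame]
    config: SimConfig
    schedule: ProtocolSchedule


def run_division(config: SimConfig, schedule: ProtocolSchedule,
                 max_time: float = 2000.0,
                 check_interval: float = 0.5,
                 frame_callback: Callable[[TrajectoryFrame], None] | None = None,
                 ) -> DivisionRun:
    """Execute a full division simulation and measure its outcome.

    Phases: relaxation, constriction protocol, disassembly, grace
    period.  The run terminates on membrane scission (division), on
    reaching ``max_time``, or — after the filament has fully
    disassembled — once the grace period has elapsed.  Reproducible:
    identical (config, schedule) give identical trajectories.
    """
    import pandas as pd

    sim = Simulation(config, schedule)
    cfg = config
    ip = cfg.integrator
    st = sim.state
    check_every = max(1, int(round(check_interval / ip.dt)))
    obs_every = max(1, int(round(cfg.obs_interval / ip.dt)))
    frame_every = (max(1, int(round(cfg.frame_interval / ip.dt)))
                   if cfg.frame_interval > 0 else 0)
    cutoff = cfg.membrane.r_cut

    rows: list[dict] = []
    frames: list[TrajectoryFrame] = []
    divided = False
    t_division = float("nan")
    t_disassembled = float("nan")
    failure = "none"
    min_d_over_d0 = np.inf
    d0 = 2.0 * cfg.vesicle_radius
    detach_min = 1.0

    def snapshot() -> TrajectoryFrame:
        fil = sim.state.filament()
        return TrajectoryFrame(
            time=st.time, mem_pos=st.mem_pos.copy(), mem_nrm=st.mem_nrm.copy(),
            fil_beads=fil.beads, fil_active=fil.active)

    def record() -> None:
        fil = sim.state.filament()
        mem = Membrane(st.mem_pos, st.mem_nrm)
        d = observables.midzone_diameter(mem.pos)
        n_comp, _ = observables.detect_division(mem.pos, cutoff)
        lo, hi = st.active_range
        tension = (observables.filament_tension(fil, st.rest,
                                                cfg.filament.spring_k)
                   if hi - lo >= 2 else float("nan"))
        rows.append({
            "time": st.time,
            "d": d,
            "d_furrow": observables.furrow_diameter(mem.pos),
            "n_components": n_comp[0],
            "tension": tension,
            "rg": (observables.radius_of_gyration(fil)
                   if hi - lo >= 2 else float("nan")),
            "perversions": (observables.count_perversions(fil)
                            if hi - lo >= 10 else 0),
            "n_active": int(st.active.sum()),
            "adsorbed_frac": observables.adsorbed_fraction(
                fil, mem, 1.5 * cfg.adhesion.r_cut_ad),
            "e_spring": sim.energies[3],
        })

    def maybe_sample() -> None:
        nonlocal min_d_over_d0, detach_min
        if st.step % obs_every == 0:
            record()
            r = rows[-1]
            if np.isfinite(r["d"]):
                min_d_over_d0 = min(min_d_over_d0, r["d"] / d0)
            if r["n_active"] > 0:
                detach_min = min(detach_min, r["adsorbed_frac"])
        if frame_every and st.step % frame_every == 0:
            fr = snapshot()
            frames.append(fr)
            if frame_callback is not None:
                frame_callback(fr)

    # phase 1: relaxation
    relax_steps = int(round(cfg.relax_time / ip.dt))
    for _ in range(relax_steps):
        sim.step()
        maybe_sample()
    sim.recenter()

    # phases 2-4
    max_steps = int(round(max_time / ip.dt))
    grace_steps = int(round(cfg.grace_time / ip.dt))
    disassembled_at_step = -1
    while st.step < max_steps:
        sim.apply_protocol()
        if sim.all_transitioned and not st.fully_disassembled:
            sim.disassemble_step()
            if st.fully_disassembled:
                disassembled_at_step = st.step
                t_disassembled = st.time
        sim.step()
        maybe_sample()
        if st.step % check_every == 0:
            sim.recenter()
            n_comp, labels = observables.detect_division(st.mem_pos, cutoff)
            if n_comp[1] >= 2:
                divided = True
                t_division = st.time
                break
        if (disassembled_at_step >= 0
                and st.step - disassembled_at_step > grace_steps):
            break

    record()
    frames.append(snapshot())

    if divided:
        n_comp, labels = observables.detect_division(st.mem_pos, cutoff)
        fil = st.filament()
        subunit_pos = np.where(st.removed_side[:, None] >= 0,
                               st.removal_pos, fil.beads[:, CORE])
        nsmall, ntotal, evenness = observables.partition_filament(
            subunit_pos, st.mem_pos, labels)
        outcome = observables.DivisionOutcome(
            divided=True, t_division=t_division, n_small=nsmall,
            n_total=ntotal, evenness=evenness, failure_mode="none",
            t_disassembled=t_disassembled)
    else:
        failure = observables.classify_failure_signals(
            final_d_over_d0=(rows[-1]["d"] / d0 if np.isfinite(rows[-1]["d"])
                             else 1.0),
            min_d_over_d0=min_d_over_d0,
            min_adsorbed_frac=detach_min,
            fully_disassembled=st.fully_disassembled)
        outcome = observables.DivisionOutcome(
            divided=False, t_division=float("nan"), n_small=0,
            n_total=st.n_subunits, evenness=float("nan"),
            failure_mode=failure, t_disassembled=t_disassembled)

    return DivisionRun(outcome=outcome, table=pd.DataFrame(rows),
                       frames=frames, config=config, schedule=schedule)


# ---------------------------------------------------------------------------
# bending-rigidity calibration
# ---------------------------------------------------------------------------

class CalibrationInvalid(RuntimeError):
    """The membrane left the fluid phase during calibration."""


def spherical_mode_amplitudes(frames: list[np.ndarray], l_max: int = 8,
                              l_min: int = 2
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-square spherical-harmonic amplitudes of radial fluctuations.

    For each frame, the relative radial displacement u = r/<r> - 1 of
    every particle is least-squares projected on real spherical
    harmonics with 2 <= l <= l_max.  Returns (l values per mode,
    per-frame |u_lm|^2 array of shape (n_frames, n_modes)).
    """
    from scipy.special import sph_harm_y

    ls = []
    for l in range(l_min, l_max + 1):
        ls.extend([l] * (2 * l + 1))
    l_arr = np.array(ls)
    amps = np.empty((len(frames), l_arr.size))
    for f, pos in enumerate(frames):
        rel = pos - pos.mean(axis=0)
        r = np.linalg.norm(rel, axis=1)
        theta = np.arccos(np.clip(rel[:, 2] / r, -1, 1))
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        u = r / r.mean() - 1.0
        cols = []
        for l in range(l_min, l_max + 1):
            for m in range(-l, l + 1):
                y = sph_harm_y(l, abs(m), theta, phi)
                if m < 0:
                    cols.append(np.sqrt(2.0) * y.imag)
                elif m == 0:
                    cols.append(y.real)
                else:
                    cols.append(np.sqrt(2.0) * y.real)
        design = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(design, u, rcond=None)
        amps[f] = coef ** 2
    return l_arr, amps


def fit_kappa_from_modes(l_arr: np.ndarray, mean_sq_amp: np.ndarray,
                         temperature: float = 1.0) -> tuple[float, float]:
    """Fit bending rigidity (and effective tension) to mode amplitudes.

    Helfrich spectrum of a quasi-spherical shell:
        <|u_lm|^2> = kBT / [kappa l(l+1)(l-1)(l+2) + sigma_eff (l-1)(l+2)].
    The inverse amplitude is linear in (kappa, sigma_eff); the linear fit
    is weighted by the amplitudes so every l contributes by its relative
    error (an unweighted fit would be dominated by the stiff high-l
    modes).  Returns (kappa, sigma_eff) in kBT units.
    """
    # average degenerate m modes per l
    uniq = np.unique(l_arr)
    y = np.array([mean_sq_amp[l_arr == l].mean() for l in uniq])
    x1 = uniq * (uniq + 1.0) * (uniq - 1.0) * (uniq + 2.0)
    x2 = (uniq - 1.0) * (uniq + 2.0)
    design = np.column_stack([x1, x2]) * y[:, None]
    coef, *_ = np.linalg.lstsq(design, np.full(uniq.size, temperature),
                               rcond=None)
    return float(coef[0]), float(coef[1])


def calibrate_bending_rigidity(membrane_params=None, radius: float = 10.0,
                               spacing: float = 0.91,
                               equil_time: float = 150.0,
                               sample_time: float = 350.0,
                               sample_interval: float = 1.0,
                               l_max: int = 6,
                               l_min: int = 3,
                               seed: int = 0,
                               n_boot: int = 200) -> tuple[float, float]:
    """Measure the emergent bending rigidity of the membrane model.

    Equilibrates a bare vesicle, samples its shape, projects radial
    fluctuations on spherical harmonics and fits the Helfrich spectrum.
    The slowest (l = 2) modes are excluded by default: starting from a
    sphere they take many hundreds of tau to reach their equilibrium
    amplitude, which biases desk-length calibrations stiff; the l >= 3
    modes equilibrate quickly and pin kappa on their own.  Returns
    (kappa estimate, bootstrap standard error) in kBT.

    Raises
    ------
    CalibrationInvalid
        If the vesicle loses particles (gas phase) or fragments.
    """
    from .params import MembraneParams, SimConfig, HelixSpec

    mp = membrane_params or MembraneParams()
    cfg = SimConfig(membrane=mp, vesicle_radius=radius,
                    vesicle_spacing=spacing,
                    helix=HelixSpec(radius=radius, n_subunits=4,
                                    n_turns=1.0, axial_width=0.0))
    sim = _membrane_only_simulation(cfg, seed)
    ip = cfg.integrator
    sim.run_steps(int(round(equil_time / ip.dt)))
    frames = []
    stride = int(round(sample_interval / ip.dt))
    n_samples = int(round(sample_time / sample_interval))
    for _ in range(n_samples):
        sim.run_steps(stride)
        frames.append(sim.state.mem_pos.copy())
    n_comp, _ = observables.detect_division(sim.state.mem_pos, mp.r_cut)
    if n_comp[0] != 1:
        raise CalibrationInvalid("vesicle fragmented during calibration")
    l_arr, amps = spherical_mode_amplitudes(frames, l_max=l_max, l_min=l_min)
    mean_amp = amps.mean(axis=0)
    kappa, _ = fit_kappa_from_modes(l_arr, mean_amp)
    boot_rng = np.random.default_rng(seed + 1)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = boot_rng.integers(0, amps.shape[0], amps.shape[0])
        k_b, _ = fit_kappa_from_modes(l_arr, amps[pick].mean(axis=0))
        boots[b] = k_b
    return kappa, float(boots.std(ddof=1))


def _membrane_only_simulation(cfg: SimConfig, seed: int) -> Simulation:
    """A Simulation whose filament is parked far away and inert."""
    sched = ProtocolSchedule(mode="instantaneous", target_ratio=1.0,
                             m_dis=0, rng_seed=seed)
    sim = Simulation(cfg, sched)
    # deactivate the (tiny) filament entirely
    st = sim.state
    st.active[:] = False
    st.fully_disassembled = True
    sim.alive[sim.n_mem:] = False
    st.sub_com += 200.0  # park far outside any cutoff
    sim._rebuild_pairs()
    sim.energies = sim._compute_forces()
    return sim
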