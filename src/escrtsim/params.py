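"""Parameter containers and configuration I/O.

All quantities are expressed in reduced units: sigma (the ~10 nm
lipid-patch diameter) for length, tau for time and kBT for energy.
Temperature is fixed to 1 kBT unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

TIMESTEP = 0.01  # tau; the curvature/disassembly rate formulas reference it


@dataclass(frozen=True)
class ReducedUnits:
    """Reduced unit system: every other quantity in the package uses these."""

    sigma: float = 1.0  # length unit, ~10 nm lipid patch
    tau: float = 1.0    # molecular-dynamics time unit
    kBT: float = 1.0    # thermal energy unit

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.tau <= 0 or self.kBT <= 0:
            raise ValueError("all reduced units must be strictly positive")


@dataclass
class HelixSpec:
    """Geometry of an ideal filament helix.

    ``axial_width`` is the total axial extent of the helix (pitch times
    number of turns).  The default two-turn, 480-subunit helix of radius
    52.5 sigma and width 6.5 sigma gives a width-to-diameter ratio of
    about 0.06.
    """

    radius: float = 52.5          # sigma
    n_turns: float = 2.0
    n_subunits: int = 480
    axial_width: float = 6.5      # sigma, total axial extent
    handedness: int = 1           # +1 right-handed, -1 left-handed

    def __post_init__(self) -> None:
        if self.n_subunits < 4:
            raise ValueError("need at least 4 subunits")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_turns <= 0:
            raise ValueError("n_turns must be positive")
        if self.axial_width < 0:
            raise ValueError("axial_width must be non-negative")
        if self.handedness not in (-1, 1):
            raise ValueError("handedness must be +1 or -1")

    @property
    def width_to_diameter(self) -> float:
        return self.axial_width / (2.0 * self.radius)

    @property
    def arc_step(self) -> float:
        """Arc length between consecutive subunits along the helix."""
        dtheta = 2.0 * np.pi * self.n_turns / self.n_subunits
        dz = self.axial_width / self.n_subunits
        return float(np.hypot(self.radius * dtheta, dz))


@dataclass
class MembraneParams:
    """One-particle-thick fluid-membrane pair potential.

    Each particle is a lipid patch carrying an outward normal; the pair
    energy has a soft repulsive core and an attraction modulated by the
    mutual alignment of the two normals, which drives self-assembly of a
    fluid sheet.  ``epsilon`` sets the attraction depth and is calibrated
    so that the emergent bending rigidity is ~15 kBT (see
    ``dynamics.calibrate_bending_rigidity``).
    """

    epsilon: float = 4.34         # kBT, depth of the pair attraction
    r_min: float = 2.0 ** (1.0 / 6.0)  # sigma, location of the energy minimum
    r_cut: float = 2.6            # sigma, attraction cutoff
    zeta: float = 4.0             # attraction-decay exponent (fluidity control)
    mu: float = 3.0               # orientation-sensitivity exponent
    theta0: float = 0.0           # spontaneous-curvature angle, radians
    # measured equilibrium nearest-neighbor spacing of the assembled fluid
    # sheet (tighter than r_min because of many-neighbor attraction)
    equilibrium_spacing: float = 0.91

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_cut):
            raise ValueError("require 0 < r_min < r_cut")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if abs(2.0 * self.zeta - round(2.0 * self.zeta)) > 1e-12:
            raise ValueError("2*zeta must be an integer")


@dataclass
class AdhesionParams:
    """Filament-membrane coupling.

    Outer (membrane-facing) beads feel a truncated-shifted 12-6 attraction
    to membrane particles; core and inner beads are purely repulsive
    (potential cut at its minimum).  The adhesion cutoff is short ranged.
    """

    epsilon_ad: float = 10.0      # kBT, outer-bead attraction depth
    sigma_ad: float = 1.0         # sigma, contact distance
    r_cut_ad: float = 2.5         # sigma, adhesion cutoff
    epsilon_rep: float = 4.0      # kBT, volume-exclusion strength

    def __post_init__(self) -> None:
        if self.r_cut_ad > 2.5 * self.sigma_ad:
            raise ValueError("adhesion must be short-ranged (cutoff <= 2.5 bead diameters)")


@dataclass
class FilamentParams:
    """Elastic filament: rigid three-bead subunits joined by nine springs."""

    spring_k: float = 600.0       # kBT/sigma^2, identical for all nine springs
    bead_sep: float = 1.0         # sigma, outer-core and core-inner separation
    bead_diameter: float = 1.0    # sigma
    target_pitch: float = 1.1     # sigma per turn of the constricted target coil


@dataclass
class IntegratorParams:
    """Langevin integrator settings.

    The timestep is fixed at 0.01 tau: the curvature-change and
    disassembly rates are defined per timestep, so changing it would
    change the meaning of the rate parameters.
    """

    dt: float = TIMESTEP          # tau
    temperature: float = 1.0      # kBT
    gamma_t: float = 1.0          # 1/tau, translational friction
    gamma_r: float = 3.0          # 1/tau, rotational friction
    max_disp: float = 0.5         # sigma, per-step instability threshold


@dataclass
class ProtocolSchedule:
    """Curvature-change and disassembly programme for one division run.

    ``mode`` selects how bond rest lengths switch from the relaxed
    (cell-radius) set to the constricted (target-radius) set:

    - ``instantaneous``: every inter-subunit bond switches at once;
    - ``sequential``: bonds switch one by one from subunit index 0,
      one bond every ``n_curv`` timesteps (rate v_curv = 1/(n 0.01 tau));
    - ``randomized``: bonds switch in a seeded uniformly random order,
      one bond every ``n_curv`` timesteps.

    Once every bond has transitioned, one subunit is removed from each
    filament end every ``m_dis`` timesteps (rate v_dis = 2/(m 0.01 tau));
    ``m_dis = 0`` disables disassembly.
    """

    mode: str = "instantaneous"
    target_ratio: float = 0.055   # R_target / R_cell
    n_curv: int = 1               # steps between bond constrictions
    m_dis: int = 2985             # steps between end-subunit removals; 0 = off
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("instantaneous", "sequential", "randomized"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if not (0 < self.target_ratio <= 1):
            raise ValueError("target_ratio must lie in (0, 1]")
        if self.mode != "instantaneous" and self.n_curv < 1:
            raise ValueError("n_curv must be >= 1")
        if self.m_dis < 0:
            raise ValueError("m_dis must be >= 0 (0 disables disassembly)")

    @property
    def v_curv(self) -> float:
        """Curvature-change rate in 1/tau (infinite for instantaneous)."""
        if self.mode == "instantaneous":
            return float("inf")
        return 1.0 / (self.n_curv * TIMESTEP)

    @property
    def v_dis(self) -> float:
        """Disassembly rate in subunits per tau (both ends combined)."""
        if self.m_dis == 0:
            return 0.0
        return 2.0 / (self.m_dis * TIMESTEP)


@dataclass
class SimConfig:
    """Full configuration of a division simulation."""

    units: ReducedUnits = field(default_factory=ReducedUnits)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    adhesion: AdhesionParams = field(default_factory=AdhesionParams)
    filament: FilamentParams = field(default_factory=FilamentParams)
    helix: HelixSpec = field(default_factory=HelixSpec)
    integrator: IntegratorParams = field(default_factory=IntegratorParams)
    vesicle_radius: float = 52.5  # sigma
    vesicle_spacing: float = 0.91  # sigma, initial lattice spacing
    relax_time: float = 50.0      # tau, pre-quench relaxation
    grace_time: float = 1000.0    # tau, post-disassembly window before failure
    obs_interval: float = 1.0     # tau, observable sampling stride
    frame_interval: float = 50.0  # tau, trajectory frame stride (0 = off)

    @classmethod
    def full_scale(cls) -> "SimConfig":
        """Full-size cell: R_cell = 52.5 sigma, 480 subunits (workstation)."""
        return cls()

    @classmethod
    def reduced_scale(cls) -> "SimConfig":
        """Desk-scale cell: R_cell = 12 sigma, 120 subunits.

        The cell radius shrinks but the filament's axial width stays at
        6.5 sigma: the subunit (bead) size is a fixed coarse-graining
        length set by the protein, and a proportionally scaled width
        would stack the helix turns within one bead diameter.
        """
        r_cell = 12.0
        return cls(
            helix=HelixSpec(radius=r_cell, n_turns=2.0, n_subunits=120,
                            axial_width=6.5),
            vesicle_radius=r_cell,
            relax_time=20.0,
            grace_time=100.0,
        )


_SECTIONS = {
    "units": ReducedUnits,
    "membrane": MembraneParams,
    "adhesion": AdhesionParams,
    "filament": FilamentParams,
    "helix": HelixSpec,
    "integrator": IntegratorParams,
}


def config_to_dict(cfg: SimConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_from_dict(data: dict) -> SimConfig:
    kwargs: dict = {}
    for key, val in data.items():
        if key in _SECTIONS:
            kwargs[key] = _SECTIONS[key](**val)
        else:
            kwargs[key] = val
    return SimConfig(**kwargs)


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML configuration; missing sections fall back to defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: SimConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
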