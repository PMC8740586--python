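"""Synthetic fixtures with machine-readable ground truth.

Every generator returns both the synthetic object and the ground truth
it was built from, so consuming tests assert recovery of known values
rather than eyeballed numbers: hemihelices with a known perversion
count, necked and split vesicles with known neck diameters and
component counts, sigmoidal constriction-curve cohorts built from a
known template, and two-peak membrane line profiles (emulating Nile-Red
staining imaged along the division axis) with known diameters.

All randomness flows through one hierarchical seeding scheme
(:func:`rng_for`), so fixture streams never collide with each other or
with simulation seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .curves import DivisionCurve, IntensityProfile
from .model import Filament, Membrane

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))   # 2.3548...

# spawn-key tags: one per fixture family
_TAG_HEMI, _TAG_NECK, _TAG_SIGMOID, _TAG_PROFILE = 11, 12, 13, 14


def rng_for(seed: int, tag: int, *extra: int) -> np.random.Generator:
    """Independent generator for (seed, fixture-family tag, indices)."""
    return np.random.default_rng(np.random.SeedSequence([seed, tag, *extra]))


@dataclass
class FixtureSpec:
    """Declarative fixture request (used by the command-line interface)."""

    kind: str                    # ideal_helix | hemihelix | split_vesicle |
                                 # necked_vesicle | sigmoid_curves | line_profiles
    params: dict = field(default_factory=dict)
    rng_seed: int = 0

    _KINDS = ("ideal_helix", "hemihelix", "split_vesicle", "necked_vesicle",
              "sigmoid_curves", "line_profiles")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")


# ---------------------------------------------------------------------------
# hemihelix
# ---------------------------------------------------------------------------

def _helix_segment(radius: float, pitch: float, turns: float,
                   handedness: int, n_pts: int):
    """One helical arc in local coordinates plus start/end frames.

    Returns (points (n,3), normals (n,3), frame_start (3,3),
    frame_end (3,3)); frames are rows (T, N, B).
    """
    # chirality flips with the sign of y alone; flipping the pitch as
    # well would give back a rotated copy of the same handedness
    c = pitch / (2.0 * np.pi)
    t = np.linspace(0.0, 2.0 * np.pi * turns, n_pts)
    s = handedness
    pts = np.column_stack([radius * np.cos(t), s * radius * np.sin(t), c * t])
    norm = np.sqrt(radius ** 2 + c ** 2)
    tang = np.column_stack([-radius * np.sin(t), s * radius * np.cos(t),
                            np.full_like(t, c)]) / norm
    nrml = np.column_stack([-np.cos(t), -s * np.sin(t), np.zeros_like(t)])
    binorm = np.cross(tang, nrml)
    def frame(k):
        return np.vstack([tang[k], nrml[k], binorm[k]])
    return pts, nrml, frame(0), frame(-1)


def make_hemihelix(segments: int, turns_per_segment: float = 2.0,
                   radius: float = 2.0, pitch: float = 1.1,
                   n_per_segment: int = 40) -> tuple[Filament, dict]:
    """Hemihelix: helical segments of alternating handedness, joined
    smoothly (continuous tangent and curvature direction at each joint).

    Returns (filament, info) where ``info['n_perversions']`` is the
    ground-truth count ``segments - 1`` and ``info['arc_length']`` the
    exact total arc length.
    """
    if segments < 1:
        raise ValueError("need at least one segment")
    all_pts = []
    all_nrm = []
    pos_offset = np.zeros(3)
    prev_end_frame = np.eye(3)   # rows (T, N, B)
    for k in range(segments):
        hand = 1 if k % 2 == 0 else -1
        pts, nrm, f0, f1 = _helix_segment(radius, pitch, turns_per_segment,
                                          hand, n_per_segment + 1)
        # rotate so the segment's start frame matches the previous end
        # frame up to the binormal flip that defines the perversion
        target = prev_end_frame.copy()
        rot = target.T @ np.vstack([f0[0], f0[1], np.cross(f0[0], f0[1])])
        pts = (pts - pts[0]) @ rot.T
        nrm = nrm @ rot.T
        tang_seg = np.vstack([f0[0], f0[1], np.cross(f0[0], f0[1])])
        pts = pts + pos_offset
        all_pts.append(pts[:-1] if k < segments - 1 else pts)
        all_nrm.append(nrm[:-1] if k < segments - 1 else nrm)
        pos_offset = pts[-1]
        end_T = rot @ f1[0]
        end_N = rot @ f1[1]
        prev_end_frame = np.vstack([end_T, end_N, np.cross(end_T, end_N)])
    core = np.vstack(all_pts)
    nrm = np.vstack(all_nrm)
    beads = np.stack([core + nrm, core, core - nrm], axis=1)
    c = pitch / (2.0 * np.pi)
    arc = segments * 2.0 * np.pi * turns_per_segment * np.sqrt(radius ** 2 + c ** 2)
    return Filament(beads=beads), {
        "n_perversions": segments - 1,
        "arc_length": float(arc),
        "segments": segments,
    }


# ---------------------------------------------------------------------------
# vesicle fixtures
# ---------------------------------------------------------------------------

def make_split_vesicle(radius: float = 10.0, separation: float = 10.0,
                       spacing: float = 0.91) -> tuple[Membrane, dict]:
    """Two disjoint spherical vesicles separated along z."""
    from .model import build_vesicle
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        single = build_vesicle(radius, spacing)
    shift = np.array([0.0, 0.0, radius + separation / 2.0])
    pos = np.vstack([single.pos + shift, single.pos - shift])
    nrm = np.vstack([single.normals, single.normals])
    return Membrane(pos=pos, normals=nrm), {"n_components": 2,
                                            "separation": separation}


def make_necked_vesicle(radius: float, neck_radius: float,
                        spacing: float = 0.91, keep_neck: bool = True
                        ) -> tuple[Membrane, dict]:
    """Dumbbell: two spherical caps joined by a smooth waist at z = 0.

    The profile rho(z) equals ``neck_radius`` exactly at the midplane
    and blends into spherical caps of radius ``radius``.  Particles are
    placed on a golden-angle spiral stratified by surface area, so the
    area density is uniform.  With ``keep_neck=False`` the waist region
    is left empty (two components).
    """
    if not (0 < neck_radius < radius):
        raise ValueError("need 0 < neck_radius < radius")
    R, rn = float(radius), float(neck_radius)
    theta1 = np.pi / 6.0                    # cap joins at 30 degrees
    rho1 = R * np.sin(theta1)
    if rn >= rho1:
        raise ValueError("neck_radius must be below R/2 for this shape")
    z1 = 0.8 * R                            # half-length of the waist
    zc = z1 + R * np.cos(theta1)            # cap sphere center height

    zmax = zc + R
    z = np.linspace(-zmax + 1e-9, zmax - 1e-9, 4001)

    def profile(zv):
        az = np.abs(zv)
        rho = np.empty_like(zv)
        waist = az <= z1
        rho[waist] = rn + (rho1 - rn) * 0.5 * (1 - np.cos(np.pi * az[waist] / z1))
        cap = ~waist
        rho[cap] = np.sqrt(np.maximum(1e-12, R ** 2 - (az[cap] - zc) ** 2))
        return rho

    rho = profile(z)
    drho = np.gradient(rho, z)
    dA = 2.0 * np.pi * rho * np.sqrt(1.0 + drho ** 2)
    cumA = np.concatenate([[0.0], np.cumsum(0.5 * (dA[1:] + dA[:-1]) * np.diff(z))])
    total = cumA[-1]
    n = int(round(total / spacing ** 2))
    frac = (np.arange(n) + 0.5) / n
    zs = np.interp(frac * total, cumA, z)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = golden * np.arange(n)
    rhos = profile(zs)
    drhos = np.interp(zs, z, drho)
    pos = np.column_stack([rhos * np.cos(phi), rhos * np.sin(phi), zs])
    denom = np.sqrt(1.0 + drhos ** 2)
    nrm = np.column_stack([np.cos(phi) / denom, np.sin(phi) / denom,
                           -drhos / denom])
    if not keep_neck:
        keep = np.abs(zs) > 0.5 * z1
        pos, nrm = pos[keep], nrm[keep]
    return Membrane(pos=pos, normals=nrm), {
        "neck_diameter": 2.0 * rn,
        "cap_radius": R,
        "n_components": 1 if keep_neck else 2,
        "area": float(total),
    }


# ---------------------------------------------------------------------------
# constriction-curve cohorts
# ---------------------------------------------------------------------------

def sigmoid_template(shape: str) -> "np.ufunc":
    """Normalized-diameter template d/d0 as a function of t/t_division.

    ``convex_release``: fast initial drop then slow plateau, as after an
    instantaneous release of stored filament tension.
    ``concave_delayed``: delayed furrow onset followed by a near-linear
    decrease, as for slow non-instantaneous constriction.
    """
    d_end = 0.25
    if shape == "convex_release":
        tau_c = 0.12
        def f(t):
            t = np.clip(np.asarray(t, float), 0.0, None)
            return d_end + (1.0 - d_end) * np.exp(-t / tau_c)
    elif shape == "concave_delayed":
        t0, w = 0.55, 0.07
        def f(t):
            t = np.asarray(t, float)
            raw = 1.0 / (1.0 + np.exp((t - t0) / w))
            r0 = 1.0 / (1.0 + np.exp(-t0 / w))
            return d_end + (1.0 - d_end) * raw / r0
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return f


def make_sigmoid_curves(n_cells: int, noise: float = 0.02,
                        shape: str = "convex_release", seed: int = 0,
                        base_d0: float = 24.0, base_t_div: float = 500.0,
                        max_shift: float = 0.05,
                        n_samples: int = 120) -> tuple[list[DivisionCurve], dict]:
    """Cohort of noisy monotone constriction curves from one template.

    Each cell gets a random initial diameter, division time and onset
    shift, plus multiplicative noise; ground truth (the template) is
    returned alongside.
    """
    if n_cells < 1:
        raise ValueError("need at least one cell")
    rng = rng_for(seed, _TAG_SIGMOID)
    template = sigmoid_template(shape)
    curves = []
    for _ in range(n_cells):
        d0 = base_d0 * rng.uniform(0.8, 1.2)
        t_div = base_t_div * rng.uniform(0.8, 1.2)
        shift = rng.uniform(-max_shift, max_shift)
        t = np.linspace(0.0, 1.0, n_samples)
        v = template(np.clip(t - shift, 0.0, 1.0))
        v = v * (1.0 + noise * rng.standard_normal(n_samples))
        curves.append(DivisionCurve(times=t * t_div, diameters=v * d0,
                                    d0=d0, t_division=t_div))
    return curves, {"shape": shape, "template": template}


# ---------------------------------------------------------------------------
# membrane line profiles
# ---------------------------------------------------------------------------

def make_line_profiles(diameters: np.ndarray, psf_fwhm: float = 2.0,
                       noise: float = 0.0, seed: int = 0,
                       halfwidth: float | None = None,
                       n_samples: int = 400,
                       background: float = 0.05
                       ) -> tuple[list[IntensityProfile], dict]:
    """Two-peak membrane intensity profiles for a diameter trajectory.

    Per frame, two Gaussian membrane edges of FWHM ``psf_fwhm`` sit at
    +-d/2, over a flat background, with Poisson-like noise of relative
    amplitude ``noise`` (SNR = 1/noise at the peak).  Ground-truth
    diameters are attached; the FWHM pipeline recovers them as
    outer-edge width minus one single-peak FWHM.
    """
    d = np.asarray(diameters, float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    rng = rng_for(seed, _TAG_PROFILE)
    s = psf_fwhm / GAUSS_FWHM
    hw = halfwidth if halfwidth is not None else 0.75 * d.max() + 6.0 * s
    x = np.linspace(-hw, hw, n_samples)
    profiles = []
    for frame, di in enumerate(d):
        signal = (np.exp(-0.5 * ((x - di / 2.0) / s) ** 2)
                  + np.exp(-0.5 * ((x + di / 2.0) / s) ** 2))
        y = background + signal
        if noise > 0:
            y = y + noise * np.sqrt(np.maximum(y, 0.0)) * \
                rng.standard_normal(x.size)
        profiles.append(IntensityProfile(positions=x.copy(),
                                         intensities=np.maximum(y, 0.0),
                                         timestamp=float(frame)))
    return profiles, {"diameters": d.copy(), "psf_fwhm": psf_fwhm,
                      "snr": (1.0 / noise if noise > 0 else np.inf)}
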