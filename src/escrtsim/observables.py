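"""Per-frame and per-run measurements.

Midzone (furrow) diameter via the Taubin algebraic circle fit, membrane
scission detection via connected components, evenness of filament
partitioning between daughters, filament tension, perversion counting
on the backbone, radius of gyration, and a local-sphere-fit membrane
curvature proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .forces import spring_tensions
from .model import CORE, Filament, Membrane


@dataclass
class DivisionOutcome:
    """Outcome of one division run.

    Evenness E = 2 N_small / N_total, where N_small counts the filament
    subunits inherited by the less-filled daughter cell: E = 1 is a
    perfectly even split, E = 0 fully asymmetric.
    """

    divided: bool
    t_division: float               # tau (nan if not divided)
    n_small: int
    n_total: int
    evenness: float                 # in [0, 1]; nan if not divided
    failure_mode: str = "none"      # none | inflated_back | detached | filament_blocks_neck
    t_disassembled: float = float("nan")

    def __post_init__(self) -> None:
        if self.divided:
            if not (0 <= self.n_small <= self.n_total / 2):
                raise ValueError("need 0 <= n_small <= n_total/2")
            expected = 2.0 * self.n_small / self.n_total
            if abs(self.evenness - expected) > 1e-9:
                raise ValueError("evenness must equal 2*n_small/n_total")


def evenness(n_small: int, n_total: int) -> float:
    """E = 2 N_small / N_total, invariant under relabeling of daughters."""
    if not (0 <= n_small <= n_total - n_small):
        raise ValueError("n_small must not exceed n_total/2")
    return 2.0 * n_small / n_total


# ---------------------------------------------------------------------------
# circle fitting and the midzone diameter
# ---------------------------------------------------------------------------

def taubin_circle_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Taubin algebraic least-squares circle fit.

    Non-iterative; exact (to machine precision) on noiseless circular
    data.  Returns (xc, yc, radius).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    xm, ym = x.mean(), y.mean()
    u, v = x - xm, y - ym
    z = u * u + v * v
    zm = z.mean()
    if zm < 1e-30:
        raise ValueError("degenerate (coincident) points")
    z0 = (z - zm) / (2.0 * np.sqrt(zm))
    design = np.column_stack([z0, u, v])
    _, _, vt = np.linalg.svd(design, full_matrices=False)
    a = vt[2]
    a0 = a[0] / (2.0 * np.sqrt(zm))
    if abs(a0) < 1e-30:
        raise ValueError("points are collinear")
    c = -zm * a0
    xc = -a[1] / (2.0 * a0)
    yc = -a[2] / (2.0 * a0)
    r2 = xc * xc + yc * yc - c / a0
    return float(xc + xm), float(yc + ym), float(np.sqrt(max(r2, 0.0)))


def midzone_diameter(mem_pos: np.ndarray, slab_width: float = 1.0,
                     axis: int = 2, center: float = 0.0) -> float:
    """Furrow diameter: Taubin circle fit of the midzone membrane slab.

    Membrane particles within the ``slab_width``-wide slab centered on
    the division plane (normal = ``axis``, fixed at the box center) are
    projected onto the plane and fitted by a circle; the diameter is
    twice the fitted radius.  Returns NaN when fewer than 6 particles
    remain in the slab (the post-scission marker).
    """
    pos = np.asarray(mem_pos, float)
    in_slab = np.abs(pos[:, axis] - center) < 0.5 * slab_width
    if int(in_slab.sum()) < 6:
        return float("nan")
    other = [d for d in range(3) if d != axis]
    pts = pos[in_slab][:, other]
    _, _, r = taubin_circle_fit(pts[:, 0], pts[:, 1])
    return 2.0 * r


def furrow_diameter(mem_pos: np.ndarray, half_range: float = 4.0,
                    n_slabs: int = 9, axis: int = 2,
                    slab_width: float = 1.0) -> float:
    """Furrow diameter: the tightest waist near the division plane.

    The fixed-plane :func:`midzone_diameter` can miss the furrow when
    the constriction ring drifts axially (relevant for small cells);
    this scans slab centers within ``half_range`` of the division plane
    and returns the smallest fitted diameter, mirroring how the
    experimental analysis follows the furrow along the division axis.
    """
    centers = np.linspace(-half_range, half_range, n_slabs)
    best = np.inf
    for c in centers:
        d = midzone_diameter(mem_pos, slab_width=slab_width, axis=axis,
                             center=float(c))
        if np.isfinite(d) and d < best:
            best = d
    return float(best) if np.isfinite(best) else float("nan")


# ---------------------------------------------------------------------------
# scission detection and partitioning
# ---------------------------------------------------------------------------

def detect_division(mem_pos: np.ndarray, cutoff: float,
                    major_fraction: float = 0.10,
                    normals: np.ndarray | None = None,
                    align_min: float = 0.0
                    ) -> tuple[tuple[int, int], np.ndarray]:
    """Connected components of the membrane adjacency graph.

    Particles are adjacent iff closer than ``cutoff`` (the membrane
    attraction cutoff).  When ``normals`` are supplied, pairs whose
    normals are anti-aligned (dot product below ``align_min``) are not
    connected: two daughter cells that remain in contact after scission
    touch through opposing outward normals, whereas a continuous sheet
    is connected through aligned in-sheet neighbors, so this detects
    scission even before the daughters drift apart.

    Returns ``((n_components, n_major), labels)`` where ``n_major``
    counts components holding at least ``major_fraction`` of all
    particles; the cell has divided when ``n_major >= 2``.  Single
    stray particles therefore never register as a division.
    """
    pos = np.asarray(mem_pos, float)
    n = pos.shape[0]
    if n == 0:
        raise ValueError("empty membrane")
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if normals is not None and len(pairs):
        nrm = np.asarray(normals, float)
        dots = np.einsum("ij,ij->i", nrm[pairs[:, 0]], nrm[pairs[:, 1]])
        pairs = pairs[dots > align_min]
    data = np.ones(len(pairs), dtype=np.int8)
    adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    counts = np.bincount(labels)
    n_major = int(np.sum(counts >= major_fraction * n))
    return (int(n_comp), n_major), labels


def divided(mem_pos: np.ndarray, cutoff: float) -> bool:
    (_, n_major), _ = detect_division(mem_pos, cutoff)
    return n_major >= 2


def partition_filament(subunit_pos: np.ndarray, mem_pos: np.ndarray,
                       labels: np.ndarray) -> tuple[int, int, float]:
    """Assign filament subunits to daughter cells and compute evenness.

    Each subunit (at its last known core position — the removal position
    for disassembled subunits, the current one otherwise) is assigned to
    the nearest of the two largest membrane components.  Equidistant
    subunits go to the smaller daughter (with a warning).  Returns
    (N_small, N_total, E).
    """
    counts = np.bincount(labels)
    if (counts >= 1).sum() < 2 or len(counts) < 2:
        raise ValueError("membrane has fewer than two components")
    big = np.argsort(counts)[::-1][:2]
    trees = [cKDTree(np.asarray(mem_pos)[labels == c]) for c in big]
    d = np.column_stack([t.query(subunit_pos)[0] for t in trees])
    ties = np.isclose(d[:, 0], d[:, 1])
    if ties.any():
        import warnings
        warnings.warn(f"{int(ties.sum())} subunits equidistant between "
                      "daughters; assigned to the smaller component",
                      stacklevel=2)
    smaller = int(np.argmin(counts[big]))
    choice = np.where(ties, smaller, np.argmin(d, axis=1))
    n_total = len(subunit_pos)
    n_first = int(np.sum(choice == 0))
    n_small = min(n_first, n_total - n_first)
    return n_small, n_total, evenness(n_small, n_total)


# ---------------------------------------------------------------------------
# filament measurements
# ---------------------------------------------------------------------------

def filament_tension(filament: Filament, rest_lengths: np.ndarray,
                     spring_k: float = 600.0) -> float:
    """Mean spring tension along the backbone [kBT/sigma].

    Mean over all active springs of the spring force projected on the
    local backbone (core-core) tangent; stretched springs contribute
    positively.
    """
    lo, hi = filament.active_range
    if hi - lo < 2:
        raise ValueError("need at least one active spring")
    out = np.empty(hi - lo - 1)
    spring_tensions(filament.beads, np.asarray(rest_lengths, float),
                    spring_k, lo, hi, out)
    return float(out.sum() / (9.0 * out.size))


def discrete_torsion(core_pos: np.ndarray, degenerate_tol: float = 1e-8
                     ) -> np.ndarray:
    """Signed discrete torsion from consecutive core-bead quadruples.

    The torsion at quadruple i is the signed dihedral angle between the
    planes of bonds (i, i+1, i+2) and (i+1, i+2, i+3); its sign encodes
    handedness.  Degenerate (collinear) quadruples yield NaN.
    """
    p = np.asarray(core_pos, float)
    b1 = p[1:-2] - p[:-3]
    b2 = p[2:-1] - p[1:-2]
    b3 = p[3:] - p[2:-1]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    m1 = np.cross(n1, b2 / b2n[:, None])
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", m1, n2)
    tau = np.arctan2(y, x)
    bad = (np.linalg.norm(n1, axis=1) < degenerate_tol) | \
          (np.linalg.norm(n2, axis=1) < degenerate_tol)
    tau[bad] = np.nan
    return tau


def count_perversions(filament: Filament, window: int = 5,
                      min_run: int = 3, tol: float = 1e-4) -> int:
    """Number of handedness reversals (perversions) along the filament.

    The discrete torsion of the active backbone is smoothed with a
    centered moving window; a perversion is a sign change between
    consecutive same-sign runs of at least ``min_run`` quadruples
    (short flickers from thermal noise are ignored).  An ideal
    single-handed helix has zero perversions.
    """
    core = filament.core_positions()
    if len(core) < 10:
        raise ValueError("need at least 10 active subunits")
    tau = discrete_torsion(core)
    tau = tau[np.isfinite(tau)]
    if tau.size < window:
        return 0
    kernel = np.ones(window) / window
    smooth = np.convolve(tau, kernel, mode="valid")
    signs = np.where(smooth > tol, 1, np.where(smooth < -tol, -1, 0))
    signs = signs[signs != 0]
    if signs.size == 0:
        return 0
    # compress to runs, drop runs shorter than min_run, count transitions
    runs: list[tuple[int, int]] = []
    cur, length = int(signs[0]), 1
    for s in signs[1:]:
        if s == cur:
            length += 1
        else:
            runs.append((cur, length))
            cur, length = int(s), 1
    runs.append((cur, length))
    kept = [s for s, ln in runs if ln >= min_run]
    merged: list[int] = []
    for s in kept:
        if not merged or merged[-1] != s:
            merged.append(s)
    return max(0, len(merged) - 1)


def radius_of_gyration(filament: Filament) -> float:
    """Mass-weighted radius of gyration of the active core beads."""
    core = filament.core_positions()
    if len(core) < 2:
        raise ValueError("need at least 2 active subunits")
    rel = core - core.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(rel * rel, axis=1))))


def adsorbed_fraction(filament: Filament, membrane: Membrane,
                      cutoff: float) -> float:
    """Fraction of active outer beads within ``cutoff`` of the membrane."""
    lo, hi = filament.active_range
    if hi - lo == 0:
        return float("nan")
    outer = filament.beads[lo:hi, 0]
    tree = cKDTree(membrane.pos)
    d, _ = tree.query(outer)
    return float(np.mean(d < cutoff))


# ---------------------------------------------------------------------------
# membrane curvature proxy
# ---------------------------------------------------------------------------

def _patch_curvature(pts: np.ndarray) -> float:
    """Mean-curvature magnitude of a local patch (osculating paraboloid).

    The patch is expressed in its PCA frame (normal = least-variance
    direction) and fitted by h = a t1^2 + b t2^2 + c t1 t2 + linear
    terms; |a + b| is the mean curvature at the patch center.  Exactly
    zero for a plane; 1/R for a sphere of radius R.
    """
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    local = centered @ vt.T          # columns: tangent1, tangent2, normal
    t1, t2, h = local[:, 0], local[:, 1], local[:, 2]
    design = np.column_stack([t1 * t1, t2 * t2, t1 * t2, t1, t2,
                              np.ones_like(t1)])
    coef, *_ = np.linalg.lstsq(design, h, rcond=None)
    return float(abs(coef[0] + coef[1]))


def membrane_deformation_proxy(mem_pos: np.ndarray,
                               neighbor_radius: float = 3.0) -> float:
    """Mean local curvature magnitude of the membrane (patch-fit proxy).

    For each particle, an osculating quadric fitted over its
    neighborhood (neighbors within ``neighbor_radius``) gives the local
    mean-curvature magnitude; particles with fewer than 6 neighbors are
    skipped.  This is a geometric proxy for membrane deformation, not a
    mechanical curvature-energy measurement; compare only its relative
    changes (e.g. to the initial vesicle's 1/R).
    """
    pos = np.asarray(mem_pos, float)
    tree = cKDTree(pos)
    neigh = tree.query_ball_point(pos, neighbor_radius)
    vals = []
    for i, idx in enumerate(neigh):
        if len(idx) < 7:   # particle itself plus >= 6 neighbors
            continue
        vals.append(_patch_curvature(pos[idx]))
    if not vals:
        raise ValueError("no particle has enough neighbors")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# failure classification signals (shared with the sweeps module)
# ---------------------------------------------------------------------------

def classify_failure_signals(final_d_over_d0: float, min_d_over_d0: float,
                             min_adsorbed_frac: float,
                             fully_disassembled: bool,
                             inflate_threshold: float = 0.9,
                             detach_threshold: float = 0.25,
                             block_threshold: float = 0.3) -> str:
    """Map run summary signals to a failure mode for undivided runs."""
    if min_adsorbed_frac < detach_threshold:
        return "detached"
    if fully_disassembled and final_d_over_d0 > inflate_threshold:
        return "inflated_back"
    if (not fully_disassembled) and final_d_over_d0 < block_threshold:
        return "filament_blocks_neck"
    return "none"
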