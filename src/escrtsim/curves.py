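"""Division-curve analysis: FWHM furrow extraction, normalization,
alignment at 50% constriction, cohort averaging, and curve comparison.

This is the pipeline used to put simulated and experimentally imaged
constriction dynamics on a common footing.  Live-cell measurements give
a membrane-intensity line profile along the division axis per frame; the
full width at half maximum (FWHM) of that profile measures the midcell
(furrow) diameter.  Each cell's diameter curve is normalized by its
initial diameter and total division time, aligned with the others at the
point of 50% constriction, resampled to a common grid and averaged.

Comparisons between mean curves are restricted to the first half of
constriction (d/d0 >= 0.5); the late phase is unreliable in experiments
(resolution limit) and in the model (molecular-scale neck geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IntensityProfile:
    """1-D membrane-intensity line profile along the division axis."""

    positions: np.ndarray     # strictly increasing, [um] or [sigma]
    intensities: np.ndarray   # non-negative
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.intensities = np.asarray(self.intensities, float)
        if self.positions.size < 8:
            raise ValueError("need at least 8 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class DivisionCurve:
    """Furrow diameter versus time for one (simulated or imaged) cell."""

    times: np.ndarray
    diameters: np.ndarray
    d0: float | None = None          # initial (pre-constriction) diameter
    t_division: float | None = None  # total division time

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.diameters = np.asarray(self.diameters, float)
        if self.times.shape != self.diameters.shape:
            raise ValueError("times and diameters must have equal length")
        if self.d0 is None:
            self.d0 = float(self.diameters[0])
        if self.t_division is None:
            self.t_division = float(self.times[-1])


@dataclass
class NormalizedCurve:
    """d/d0 on the common normalized-time grid (NaN where undefined)."""

    grid: np.ndarray          # t / t_division in [0, 1]
    values: np.ndarray        # d / d0


class FwhmUndefined(ValueError):
    """The profile has no half-maximum crossing on one side."""


def fwhm(profile: IntensityProfile, background_fraction: float = 0.1
         ) -> float:
    """Full width at half maximum of a line profile.

    The background (median of the outer ``background_fraction`` of
    samples on each side) is subtracted; the width is measured between
    the outermost crossings of half the peak height, with linear
    interpolation between samples.  For a two-peak membrane profile this
    returns the outer-edge width — the cell's outer diameter plus one
    single-peak FWHM.

    Raises
    ------
    FwhmUndefined
        If the profile never rises above half maximum or a crossing is
        missing on either side.
    """
    x = profile.positions
    y = profile.intensities.astype(float)
    n_bg = max(1, int(round(background_fraction * y.size / 2)))
    background = np.median(np.concatenate([y[:n_bg], y[-n_bg:]]))
    y = y - background
    peak = y.max()
    if peak <= 0:
        raise FwhmUndefined("profile has no peak above background")
    half = 0.5 * peak
    above = y >= half
    if not above.any() or above[0] or above[-1]:
        raise FwhmUndefined("no half-maximum crossing on one side")
    first = int(np.argmax(above))
    last = int(y.size - 1 - np.argmax(above[::-1]))
    # linear interpolation to the exact crossing on each side
    x_left = np.interp(half, [y[first - 1], y[first]],
                       [x[first - 1], x[first]])
    x_right = np.interp(half, [y[last + 1], y[last]],
                        [x[last + 1], x[last]])
    return float(x_right - x_left)


def diameter_from_profile(profile: IntensityProfile, psf_fwhm: float,
                          background_fraction: float = 0.1) -> float:
    """Furrow diameter from a two-peak membrane profile.

    The outer-edge FWHM of a profile with two membrane peaks separated
    by the diameter d is d plus one single-peak FWHM; subtracting the
    optical single-peak width (``psf_fwhm``) recovers d.
    """
    return fwhm(profile, background_fraction) - psf_fwhm


def _crossing_time(t: np.ndarray, v: np.ndarray, level: float) -> float:
    """First downward crossing of ``level``, linearly interpolated."""
    below = v <= level
    if not below.any():
        raise ValueError("curve never crosses the level")
    k = int(np.argmax(below))
    if k == 0:
        return float(t[0])
    return float(np.interp(level, [v[k], v[k - 1]], [t[k], t[k - 1]]))


def normalize_and_align(curves: list[DivisionCurve], n_grid: int = 101,
                        align_level: float = 0.5,
                        ) -> tuple[list[NormalizedCurve], NormalizedCurve,
                                   NormalizedCurve]:
    """Normalize, align at 50% constriction, and average a cohort.

    Each curve is rescaled to d/d0 versus t/t_division (so the result is
    invariant to the physical units of either axis), time-shifted so
    that every curve crosses ``align_level`` at the cohort-mean crossing
    time, and resampled to a common ``n_grid``-point grid on [0, 1].
    Curves that never reach the alignment level are excluded with a
    warning.

    Returns (normalized curves, pointwise mean, pointwise SD); mean and
    SD are NaN where no curve is defined.
    """
    normed: list[tuple[np.ndarray, np.ndarray, float]] = []
    for i, c in enumerate(curves):
        t = c.times / c.t_division
        v = c.diameters / c.d0
        try:
            t_half = _crossing_time(t, v, align_level)
        except ValueError:
            import warnings
            warnings.warn(f"curve {i} never reaches {align_level:.0%} "
                          "constriction; excluded", stacklevel=2)
            continue
        normed.append((t, v, t_half))
    if not normed:
        raise ValueError("no curve reaches the alignment level")
    t_anchor = float(np.mean([h for _, _, h in normed]))
    grid = np.linspace(0.0, 1.0, n_grid)
    out = []
    for t, v, t_half in normed:
        ts = t + (t_anchor - t_half)
        vals = np.interp(grid, ts, v, left=np.nan, right=np.nan)
        out.append(NormalizedCurve(grid=grid, values=vals))
    stack = np.vstack([c.values for c in out])
    with np.errstate(invalid="ignore"):
        any_def = np.any(np.isfinite(stack), axis=0)
        mean = np.where(any_def, np.nanmean(stack, axis=0), np.nan)
        sd = np.where(any_def, np.nanstd(stack, axis=0, ddof=0), np.nan)
    return out, NormalizedCurve(grid, mean), NormalizedCurve(grid, sd)


def compare_to_reference(mean_sim: NormalizedCurve,
                         mean_ref: NormalizedCurve) -> float:
    """RMS difference between two mean curves over the first half.

    Only grid points where the reference is at or above 50% of the
    initial diameter (and both curves are defined) enter the score: the
    late, sub-50% tail is excluded by construction.  The score is
    symmetric and zero for identical curves; it ranks protocols, it is
    not a fit.
    """
    if mean_sim.grid.shape != mean_ref.grid.shape or \
            not np.allclose(mean_sim.grid, mean_ref.grid):
        raise ValueError("curves must share a common grid")
    a, b = mean_sim.values, mean_ref.values
    mask = np.isfinite(a) & np.isfinite(b) & (a >= 0.5) & (b >= 0.5)
    if not mask.any():
        raise ValueError("no overlapping first-half samples")
    diff = a[mask] - b[mask]
    return float(np.sqrt(np.mean(diff * diff)))


def drop_aligned_curve(times: np.ndarray, diameters: np.ndarray,
                       n_grid: int = 101, anchor: float = 0.5,
                       median_window: int = 5) -> NormalizedCurve:
    """Shape of a constriction transient, rescaled by its own total drop.

    For runs that do not constrict all the way (e.g. scaled-down cells),
    the shape of the descent still distinguishes an instantaneous
    release (convex: fast drop, then plateau) from slow distributed
    constriction (concave: delayed onset).  The diameter is mapped to
    the relative drop (d - d_min)/(d0 - d_min) in [0, 1], time is
    normalized by the transient duration, and the curve is shifted so
    its half-drop crossing sits at ``anchor`` on the common grid.
    Passing both a simulated curve and a template through this function
    makes them directly comparable with :func:`compare_to_reference`.
    """
    t = np.asarray(times, float)
    d = np.asarray(diameters, float)
    keep = np.isfinite(d)
    t, d = t[keep], d[keep]
    if median_window > 1:
        # the slab circle fit occasionally glitches when the waist is
        # strongly non-circular; a running median removes the spikes
        from scipy.ndimage import median_filter
        d = median_filter(d, size=median_window, mode="nearest")
    # the transient may begin dropping immediately (instantaneous
    # release), so the initial level is the early maximum, not the mean
    n0 = max(1, int(0.05 * d.size))
    d0 = float(d[:n0].max())
    i_min = int(np.argmin(d))
    t_end = t[i_min] if i_min > 0 else t[-1]
    d_min = float(d[:i_min + 1].min())
    if d_min >= d0:
        raise ValueError("curve does not constrict")
    tt = (t - t[0]) / (t_end - t[0])
    rel = (d - d_min) / (d0 - d_min)
    t_half = _crossing_time(tt, rel, 0.5)
    grid = np.linspace(0.0, 1.0, n_grid)
    vals = np.interp(grid, tt + (anchor - t_half), rel,
                     left=np.nan, right=np.nan)
    return NormalizedCurve(grid=grid, values=vals)


def curve_from_table(times: np.ndarray, diameters: np.ndarray,
                     d0: float | None = None) -> DivisionCurve:
    """Build a DivisionCurve from a (t, d) table, dropping NaN diameters.

    ``d0`` defaults to the mean diameter over the first 5% of samples
    (the pre-constriction plateau).
    """
    t = np.asarray(times, float)
    d = np.asarray(diameters, float)
    keep = np.isfinite(d)
    t, d = t[keep], d[keep]
    if t.size < 2:
        raise ValueError("fewer than two finite samples")
    if d0 is None:
        n0 = max(1, int(0.05 * d.size))
        d0 = float(d[:n0].mean())
    return DivisionCurve(times=t, diameters=d, d0=d0, t_division=float(t[-1]))
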