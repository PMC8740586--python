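# Methods

This note documents the model implemented by `escrtsim`, the choices
made where the design was genuinely open, and what the synthetic data
and the scaled-down test conditions do and do not establish.

## The physical model

**Cell membrane.** The cell is a closed vesicle of orientation-carrying
particles, each representing a ~10 nm patch of lipid bilayer (the
reduced length unit sigma). Particle pairs interact through a
one-particle-thick anisotropic potential: a soft repulsive core for
r < r_min = 2^(1/6) sigma and, out to r_cut = 2.6 sigma, an attraction
of depth epsilon modulated by the factor

    phi = 1 + mu (a - 1),
    a = n_i . n_j - (n_i . r_hat)(n_j . r_hat)
        + sin(theta0) (n_j - n_i) . r_hat - sin^2(theta0),

which is maximal for coplanar aligned normals. With the defaults
(epsilon = 4.34 kBT, mu = 3, zeta = 4, theta0 = 0) the particles
self-assemble into a fluid sheet. The membrane is specified by its
emergent elasticity, not by its microscopic parameters: the
fluctuation-spectrum calibration (below) measures a bending rigidity of
kappa ~ 15 kBT for the default parameterization, the physiological
value targeted by the model. The attraction depth is the calibration
knob; the remaining exponents control fluidity and are held at values
for which the sheet is demonstrably fluid (particles diffuse, the
vesicle reseals pores).

The equilibrium nearest-neighbor spacing of the assembled sheet is
~0.91 sigma — noticeably below the pair minimum at 1.12 sigma, because
each particle binds several neighbors. Vesicles are therefore seeded on
a Fibonacci lattice at 0.91 sigma spacing so the initial radius is the
relaxed radius; seeding at the pair-minimum spacing makes the vesicle
shrink ~14% while it sheds excess area.

**Filament.** The ESCRT-III polymer is a chain of rigid three-bead
subunits: an adhesive outer bead facing the membrane, a core bead, and
an inert inner bead, collinear and spaced one bead diameter (1 sigma)
apart. Consecutive subunits are joined by nine harmonic springs (every
bead-bead pair) with K = 600 kBT/sigma^2; the nine rest lengths are the
bead-bead distances measured on an ideal helix, so the rest-length set
encodes a target geometry. The default initial state is a two-turn
helix of 480 subunits with total axial width 6.5 sigma whose radius
equals the cell radius R_cell = 52.5 sigma (width-to-diameter ratio
6.5/105 ~ 0.06). Outer beads adhere to membrane particles through a
truncated-shifted 12-6 potential (depth epsilon_ad, cutoff 2.5 sigma);
core and inner beads, and non-bonded filament beads among themselves,
interact by purely repulsive volume exclusion.

**Dynamics.** Everything evolves by underdamped Langevin dynamics
(BAOAB splitting, exact Ornstein-Uhlenbeck friction step) at kBT = 1
with a timestep of 0.01 tau — the timestep is part of the model
definition because the constriction and disassembly rates are defined
per timestep. Membrane orientations and rigid subunits carry angular
velocities; rotational inertia is isotropic, which leaves every
equilibrium average unchanged and only rescales rotational relaxation
times. Friction defaults are gamma_t = 1/tau and gamma_r = 3/tau.
Forces are evaluated through a cell list whose cells are at least as
large as the largest cutoff, so no interacting pair is ever missed;
the kernel is verified against an O(N^2) reference evaluation of the
closed-form potentials.

**Constriction protocols.** Division is driven by switching each
consecutive pair's nine rest lengths from the initial (cell-radius) set
to a target set measured on a tight helix of radius
R_target = target_ratio x R_cell. The target helix preserves the arc
length per subunit (the filament is inextensible) and stacks its turns
with an axial pitch of 1.1 sigma per turn, just above one bead
diameter, so successive turns of the target coil touch without
interpenetrating. Three protocols order the switches: `instantaneous`
(all pairs in a single step), `sequential` (one pair every n steps from
the index-0 end; rate v_curv = 1/(n 0.01 tau)), and `randomized` (one
pair every n steps in a seeded uniformly random order). Once all pairs
have switched, one subunit is removed from each filament end every m
steps (v_dis = 2/(m 0.01 tau); m = 0 disables disassembly). Removal
deactivates the subunit's springs, adhesion and excluded volume; its
last position is recorded for partition accounting.

**Initial placement.** The ring is placed just inside the vesicle wall:
the outer beads sit one adhesion contact distance inside the sphere
even at the helix ends, and the placement helix spans proportionally
more turns so that the arc length per subunit equals the rest
geometry's — the filament starts bent slightly inward but unstretched.
A short relaxation precedes the protocol.

## Observables

- **Midzone (furrow) diameter**: membrane particles inside a 1-sigma
  slab about the division plane (perpendicular to the initial helix
  axis, through the membrane center of mass — the frame is recentred
  on the membrane so the slab stays on the cell) are projected onto the
  plane and fitted with the Taubin algebraic circle fit, which is exact
  on noiseless circles and agrees with iterative geometric fits to
  <0.1% at realistic noise. Diameter = 2 x fitted radius; fewer than 6
  particles in the slab marks the post-scission state.  A companion
  furrow tracker returns the minimum fitted diameter over slabs within
  4 sigma of the division plane: in small cells the constriction ring
  drifts axially, and the fixed-plane measurement can miss the furrow;
  the tracked value mirrors how the experimental analysis follows the
  furrow along the division axis.
- **Scission detection**: connected components of the membrane
  adjacency graph (edge iff distance < the attraction cutoff); divided
  means at least two components each holding >= 10% of particles, so
  stray evaporated particles never count. Because daughter cells stay
  in contact after scission (nothing pushes them apart), the driver
  additionally cuts edges between particles whose normals are
  anti-aligned: two touching outer surfaces meet through opposing
  normals, whereas a continuous sheet is connected through aligned
  in-sheet neighbors. The distance-only graph is the default for
  separated objects and constructed fixtures.
- **Partition evenness**: each subunit, at its removal position (or its
  final position if never removed), is assigned to the nearest of the
  two largest membrane components; E = 2 N_small / N_total, 1 = even.
- **Filament tension**: mean over all active springs of the spring
  force projected on the local core-core tangent; stretched springs
  count positive.
- **Perversions**: the signed discrete torsion of four consecutive core
  beads, smoothed with a centered 5-point window; a perversion is a
  sign change between same-sign runs of at least 3 smoothed samples
  (shorter runs are thermal flicker). Exact on constructed hemihelices
  with up to 6 segments and zero on ideal helices.
- **Membrane deformation proxy**: mean magnitude of the local mean
  curvature from an osculating-paraboloid fit over each particle's
  3-sigma neighborhood (the algebraic sphere fit is degenerate for flat
  patches). This is a geometric proxy; only its relative changes are
  meaningful.

## Bending-rigidity calibration

A bare vesicle (default radius 10 sigma, ~1500 particles) is
equilibrated and sampled; the relative radial displacement field is
projected on real spherical harmonics and the Helfrich spectrum

    <|u_lm|^2> = kBT / [kappa l(l+1)(l-1)(l+2) + sigma_eff (l-1)(l+2)]

is fitted for kappa and an effective tension, weighting each l by its
amplitude so that every mode contributes by relative error. The
calibration fits 3 <= l <= 6 by default: starting from a seeded
sphere, the l = 2 modes take many hundreds of tau to grow to their
equilibrium amplitude, which biases short calibrations stiff, while
the l >= 3 modes equilibrate quickly and pin kappa on their own. The
estimator recovers kappa = 15 +- 1 from synthetic spectra drawn at
kappa = 15, and the default membrane parameterization measures
kappa ~ 16-17 +- 0.5 kBT in 350-tau desk calibrations (within the
targeted physiological band). Bootstrap resampling over frames
supplies the standard error; fragmentation or evaporation of the
vesicle invalidates the calibration.

## Curve analysis

The comparison pipeline mirrors how live-cell furrow dynamics are
quantified: the membrane-dye intensity profile along the division axis
has two peaks (the two membrane edges); the full width at half maximum
of the background-subtracted profile measures the outer diameter plus
one single-peak width, which is subtracted. Each cell's diameter curve
is normalized by its initial diameter and total division time, aligned
with the cohort at the 50% crossing (linear interpolation), resampled
to a common 101-point grid, and averaged pointwise. Curve comparisons
use the RMS difference restricted to the first half of constriction
(d/d0 >= 0.5); the late phase is excluded structurally because it is
unreliable both in experiments (resolution limit) and in the model
(molecular-scale neck geometry).

## Synthetic data

The fixture generators produce every input class with attached ground
truth: hemihelices built from analytically joined helical arcs of
alternating chirality (known perversion count and arc length); necked
and split vesicles sampled uniformly by surface area (known neck
diameter and component count); cohorts of noisy monotone constriction
curves from two templates — `convex_release` (exponential drop then
plateau, the signature of an instantaneous tension release) and
`concave_delayed` (delayed onset then near-linear decrease, the
signature of slow distributed constriction) — with random initial
diameters, division times and onset shifts; and two-peak Gaussian line
profiles with Poisson-like noise emulating membrane-stained imaging.
What these fixtures do *not* emulate: optical sectioning, uneven
staining, cell motion during acquisition, or segmentation errors —
passing recovery tests on them validates the measurement pipeline's
arithmetic, not its robustness to real microscopy artifacts.

## Scaled-down study conditions

The full-size system (R_cell = 52.5 sigma, 480 subunits, ~41,000
membrane particles) is a workstation-scale computation. The package's
test and demonstration preset shrinks the cell to R_cell = 12 sigma
with 120 subunits (~2,200 membrane particles), keeping the filament's
axial width at 6.5 sigma because the subunit size is a fixed
coarse-graining length — a proportionally scaled width would stack the
helix turns within one bead diameter. Two consequences matter when
interpreting reduced-cell results:

- the quench depth does not transfer: the full-size dividing regime
  (R_target/R_cell ~ 5%) corresponds to a sub-bead target radius at
  R_cell = 12, which is geometrically unreachable; the reduced preset
  therefore uses a proportionally deeper *absolute* coil (target ratio
  ~ 0.15, R_target ~ 1.8 sigma) chosen by a calibration sweep as the
  most constricting stable setting;
- the ratio of coil size to cell size is ~4x larger than at full
  scale, so the relative constriction d/d0 bottoms out near 0.5-0.6
  rather than ~0.1, and the small daughter lobes re-inflate a vacated
  neck faster.

Reduced-cell runs reproduce the mechanistic sequence — supercoiling
into a hemihelix with perversions, membrane furrowing, tension
build-up and decay, the detachment failure mode at weak adhesion, and
re-inflation when disassembly outruns constriction — and are used for
ordering/shape assertions, not for quantitative reproduction of
full-scale reliability values.

## Numerical choices and conventions

- Timestep fixed at 0.01 tau (rate definitions depend on it);
  integration is aborted with a diagnostic if any particle moves more
  than 0.5 sigma in one step.
- Cell-list grids are capped at 128 cells per dimension (cells grow
  beyond the cutoff instead; correctness is preserved) so a runaway
  particle cannot exhaust memory.
- The hot kernels are compiled with fastmath; trajectories are
  bit-reproducible for a given seed on a given platform/build, which is
  the documented determinism contract.
- Sequential constriction starts at subunit index 0 (arbitrary by
  symmetry, fixed for reproducibility).
- Failure classification thresholds (re-inflation above 0.9 d0,
  adsorbed fraction below 0.25, blocking plateau below 0.3 d0) are
  classifier conventions validated on constructed trajectories and
  exposed as arguments; they are stable to +-10% perturbation on those
  fixtures.
- Grace period after full disassembly before a run is declared over:
  1000 tau at full scale, 100 tau reduced (re-inflation of a vacated
  reduced-cell neck completes well within that window).
- Shape comparisons of partial transients (`curves.drop_aligned_curve`)
  median-filter the diameter series (the slab circle fit occasionally
  glitches on strongly non-circular waists), take the early maximum as
  the initial level (the drop can begin immediately), rescale by the
  curve's own total drop, and align curves at their half-drop point.

## Known limitations

- No hydrodynamics, no explicit solvent, no volume constraint on the
  vesicle; timescales are therefore not mapped to physical minutes.
- The one-particle-thick membrane cannot capture bilayer-resolution
  details of the final scission geometry, and its self-healing is
  strong: bare necks down to ~1.5 sigma waist radius reseal and reopen
  rather than divide on accessible timescales. Complete topological
  scission at reduced scale is correspondingly rare; see the
  discussion of scale above.
- The membrane-curvature observable is a geometric proxy; its absolute
  values are not comparable to energy-based curvature measures.
- Absolute FWHM values depend on the background-subtraction convention
  (median of the outer 10% of samples) and should not be compared
  across conventions.
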