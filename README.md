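# escrtsim

Coarse-grained simulation of ESCRT-III–driven cell division in archaea,
together with the measurement pipeline used to compare simulated
constriction dynamics with live-cell imaging.

In TACK archaea such as *Sulfolobus acidocaldarius*, cytokinesis is
performed by an ESCRT-III filament ring (CdvB1/2) adsorbed on the inside
of the cell membrane. Once its template ring is degraded, the filament's
preferred radius of curvature drops from the cell radius R_cell to a
much smaller R_target, and the filament is disassembled from both ends.
`escrtsim` implements a particle-based model of this machine:

- the **membrane** is a one-particle-thick fluid sheet of
  orientation-carrying particles (one particle ≈ a 10 nm lipid patch,
  the length unit σ) whose anisotropic pair potential self-assembles
  into vesicles with bending rigidity κ ≈ 15 kBT;
- the **filament** is a chain of rigid three-bead subunits (adhesive
  outer bead, core, inert inner bead) joined by nine harmonic springs
  per consecutive pair, K = 600 kBT/σ²; the spring rest lengths encode
  the target helix geometry, so switching them from the R_cell set to
  the R_target set is the constriction signal;
- everything evolves by Langevin dynamics at kBT = 1 with timestep
  0.01 τ. Constriction protocols (`instantaneous`, `sequential`,
  `randomized`; rate v_curv = 1/(n·0.01 τ)) order the rest-length
  switches; disassembly removes one subunit from each end every m steps
  (v_dis = 2/(m·0.01 τ)).

The packaged observables are those used to characterize division: the
midzone (furrow) diameter from a Taubin circle fit of the equatorial
membrane slab, scission detection from membrane connectivity, evenness
of filament partitioning E = 2·N_small/N_total, filament tension,
perversion (handedness-kink) counts along the backbone, radius of
gyration, and a local-curvature proxy. The `curves` module implements
the experiment-facing pipeline: FWHM furrow extraction from
membrane-intensity line profiles, normalization by initial diameter and
division time, alignment at 50% constriction, cohort averaging, and
first-half RMS comparison between mean curves.

## Worked example

```python
import numpy as np
from escrtsim import SimConfig, ProtocolSchedule, run_division
from escrtsim.curves import drop_aligned_curve, compare_to_reference
from escrtsim.fixtures import make_sigmoid_curves

cfg = SimConfig.reduced_scale()          # desk-size cell: R=12 sigma, 120 subunits
sched = ProtocolSchedule(mode="instantaneous", target_ratio=0.15,
                         m_dis=0, rng_seed=5)
run = run_division(cfg, sched, max_time=130.0)
tab = run.table[run.table["time"] >= cfg.relax_time]
print(f"d0 = {tab['d_furrow'].iloc[0]:.1f} sigma, "
      f"min d = {tab['d_furrow'].min():.1f} sigma, "
      f"perversions at end = {int(tab['perversions'].iloc[-1])}")

curve = drop_aligned_curve(tab["time"].to_numpy(),
                           tab["d_furrow"].to_numpy())
for shape in ("convex_release", "concave_delayed"):
    cs, _ = make_sigmoid_curves(1, noise=0.0, max_shift=0.0, shape=shape)
    t = drop_aligned_curve(cs[0].times, cs[0].diameters)
    print(f"RMS vs {shape}: {compare_to_reference(curve, t):.3f}")
```

prints (exact numbers for this seed):

```
d0 = 19.2 sigma, min d = 12.6 sigma, perversions at end = 5
RMS vs convex_release: 0.272
RMS vs concave_delayed: 0.347
```

The instantaneous quench coils the filament into a hemihelix (the
nonzero perversion count) and pulls the furrow in from 19 σ to 13 σ
within a few τ of the release — the convex fast-drop-then-plateau
transient of a released spring, and the RMS scores rank it closer to
the convex template. The slow `sequential`/`randomized` protocols
produce the opposite ordering (delayed-onset concave transients,
scoring ~0.04–0.1 against the concave template versus ~0.16–0.2
against the convex one).

The same machinery runs from the shell:

```
escrtsim simulate --protocol randomized --target-ratio 0.15 \
    --n-curv 80 --m-dis 300 --seed 1 --out out/
escrtsim sweep sweep.yaml --out sweep_out/
escrtsim fixtures line_profiles --out profiles.csv
escrtsim curves cells.csv --reference sim_cells.csv
```

Full-size runs (R_cell = 52.5 σ, 480 subunits, ~41,000 membrane
particles) use `SimConfig.full_scale()` and are workstation-scale
computations; see `docs/methods.md` for what the reduced cell does and
does not reproduce.

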