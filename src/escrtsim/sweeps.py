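"""Seed-replicated parameter sweeps over division protocols.

Reproduces the phase-diagram experiments: division probability and
evenness over a 2-D grid of schedule parameters (e.g. target radius
ratio x disassembly rate for the instantaneous protocol, or curvature
rate x disassembly rate for sequential/randomized), with several random
seeds per grid cell.  Results are a pure function of (spec, seeds):
cells may be executed in any order and can be resumed from a cache.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .dynamics import DivisionRun, InstabilityError, run_division
from .params import ProtocolSchedule, SimConfig


@dataclass
class SweepSpec:
    """A 2-D grid of protocol parameters with seed replicates per cell."""

    mode: str                                   # protocol mode for all cells
    axis1: str                                  # ProtocolSchedule field name
    values1: tuple
    axis2: str
    values2: tuple
    seeds: int = 10
    base_seed: int = 0
    fixed: dict = field(default_factory=dict)   # extra schedule fields
    max_time: float = 2000.0

    def __post_init__(self) -> None:
        if len(self.values1) == 0 or len(self.values2) == 0:
            raise ValueError("axis grids must be nonempty")
        if self.seeds < 1:
            raise ValueError("need at least one seed per cell")

    def schedule_for(self, i: int, j: int, rep: int) -> ProtocolSchedule:
        """The fully determined schedule of one replicate (pure function)."""
        seed = int(np.random.SeedSequence(
            [self.base_seed, i, j, rep]).generate_state(1)[0] % (2 ** 31))
        kwargs = dict(self.fixed)
        kwargs[self.axis1] = self.values1[i]
        kwargs[self.axis2] = self.values2[j]
        return ProtocolSchedule(mode=self.mode, rng_seed=seed, **kwargs)


def classify_failure(run: DivisionRun,
                     inflate_threshold: float = 0.9,
                     detach_threshold: float = 0.25,
                     block_threshold: float = 0.3) -> str:
    """Failure mode of an undivided run, from its observable table.

    - ``inflated_back``: the cell returned above ``inflate_threshold``
      of its initial diameter after the filament fully disassembled;
    - ``detached``: the adsorbed fraction of outer beads dropped below
      ``detach_threshold`` before maximum constriction was reached;
    - ``filament_blocks_neck``: the diameter plateaued below
      ``block_threshold`` of initial with filament still present;
    - ``none`` otherwise.

    The thresholds are classifier conventions (validated on constructed
    fixtures), not measured quantities.
    """
    if run.outcome.divided:
        return "none"
    tab = run.table
    d0 = 2.0 * run.config.vesicle_radius
    d = tab["d"].to_numpy()
    finite = np.isfinite(d)
    if not finite.any():
        return "none"
    rel = d[finite] / d0
    i_min = int(np.argmin(rel))
    adsorbed = tab["adsorbed_frac"].to_numpy()[finite][:i_min + 1]
    if adsorbed.size and np.nanmin(adsorbed) < detach_threshold:
        return "detached"
    fully_dis = bool(run.outcome.t_disassembled == run.outcome.t_disassembled)
    if fully_dis and rel[-1] > inflate_threshold:
        return "inflated_back"
    n_active_end = int(tab["n_active"].to_numpy()[-1])
    if rel[i_min:].min() < block_threshold and n_active_end > 0:
        return "filament_blocks_neck"
    return "none"


@dataclass
class SweepResult:
    spec: SweepSpec
    table: pd.DataFrame          # one row per replicate (tidy long format)

    def aggregate(self) -> pd.DataFrame:
        """Per-cell division probability, mean evenness, failure tallies."""
        rows = []
        for (v1, v2), grp in self.table.groupby([self.spec.axis1,
                                                 self.spec.axis2], sort=False):
            div = grp["divided"]
            rows.append({
                self.spec.axis1: v1,
                self.spec.axis2: v2,
                "n": len(grp),
                "p_division": float(div.mean()),
                "mean_evenness": (float(grp.loc[div, "evenness"].mean())
                                  if div.any() else float("nan")),
                **{f"n_{m}": int((grp["failure_mode"] == m).sum())
                   for m in ("inflated_back", "detached",
                             "filament_blocks_neck", "none", "unstable")},
            })
        return pd.DataFrame(rows)

    def probability_grid(self) -> np.ndarray:
        agg = self.aggregate()
        grid = np.full((len(self.spec.values1), len(self.spec.values2)),
                       np.nan)
        for _, row in agg.iterrows():
            i = list(self.spec.values1).index(row[self.spec.axis1])
            j = list(self.spec.values2).index(row[self.spec.axis2])
            grid[i, j] = row["p_division"]
        return grid


def _cell_key(spec: SweepSpec, config: SimConfig, i: int, j: int,
              rep: int) -> str:
    payload = json.dumps({
        "mode": spec.mode, "a1": spec.axis1, "v1": spec.values1[i],
        "a2": spec.axis2, "v2": spec.values2[j], "rep": rep,
        "base_seed": spec.base_seed, "fixed": spec.fixed,
        "max_time": spec.max_time,
        "config": repr(config),
    }, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:20]


def run_sweep(spec: SweepSpec, config: SimConfig | None = None,
              runner: Callable[..., DivisionRun] = run_division,
              cache_dir: str | Path | None = None,
              progress: bool = False) -> SweepResult:
    """Execute every replicate of the sweep grid.

    ``runner`` (default :func:`escrtsim.dynamics.run_division`) can be
    replaced by a stub for bookkeeping tests.  With ``cache_dir``,
    completed replicates are skipped on rerun (keyed by a content hash
    of the cell's full parameterization).  An unstable replicate is
    recorded with ``failure_mode='unstable'`` and the sweep continues.
    """
    config = config or SimConfig.reduced_scale()
    cache = Path(cache_dir) if cache_dir is not None else None
    if cache is not None:
        cache.mkdir(parents=True, exist_ok=True)
    rows = []
    cells = [(i, j, rep)
             for i in range(len(spec.values1))
             for j in range(len(spec.values2))
             for rep in range(spec.seeds)]
    iterator = cells
    if progress:
        from tqdm import tqdm
        iterator = tqdm(cells, desc="sweep")
    for i, j, rep in iterator:
        key = _cell_key(spec, config, i, j, rep)
        if cache is not None and (cache / f"{key}.json").exists():
            rows.append(json.loads((cache / f"{key}.json").read_text()))
            continue
        sched = spec.schedule_for(i, j, rep)
        row = {
            spec.axis1: spec.values1[i],
            spec.axis2: spec.values2[j],
            "replicate": rep,
            "seed": sched.rng_seed,
        }
        try:
            run = runner(config, sched, max_time=spec.max_time)
            row.update({
                "divided": bool(run.outcome.divided),
                "evenness": float(run.outcome.evenness),
                "t_division": float(run.outcome.t_division),
                "failure_mode": classify_failure(run),
            })
        except InstabilityError:
            row.update({"divided": False, "evenness": float("nan"),
                        "t_division": float("nan"),
                        "failure_mode": "unstable"})
        if cache is not None:
            (cache / f"{key}.json").write_text(json.dumps(row, default=str))
        rows.append(row)
    table = pd.DataFrame(rows)
    return SweepResult(spec=spec, table=table)
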