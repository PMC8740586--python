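"""Trajectory, table and checkpoint I/O.

Snapshots are written as extended-XYZ text frames (positions, normal
vectors and bead-type labels) readable by standard molecular viewers;
observable tables as CSV; outcomes as JSON; checkpoints as NumPy
archives carrying the full simulation state including the RNG state.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

# species labels: membrane, outer (adhesive), core, inner filament beads
SPECIES = ("M", "O", "C", "I")


def write_extxyz_frame(fh, pos: np.ndarray, species: list[str] | np.ndarray,
                       normals: np.ndarray | None = None,
                       time: float | None = None,
                       comment_extra: str = "") -> None:
    """Append one extended-XYZ frame to an open text file."""
    n = len(pos)
    props = "species:S:1:pos:R:3"
    if normals is not None:
        props += ":normal:R:3"
    header = f'Properties={props}'
    if time is not None:
        header += f" Time={time:.4f}"
    if comment_extra:
        header += " " + comment_extra
    fh.write(f"{n}\n{header}\n")
    for k in range(n):
        line = (f"{species[k]} {pos[k, 0]:.6f} {pos[k, 1]:.6f} "
                f"{pos[k, 2]:.6f}")
        if normals is not None:
            line += (f" {normals[k, 0]:.6f} {normals[k, 1]:.6f} "
                     f"{normals[k, 2]:.6f}")
        fh.write(line + "\n")


def write_frame(path: str | Path, frame, mode: str = "a") -> None:
    """Write one dynamics.TrajectoryFrame as extended XYZ (append)."""
    mem_n = len(frame.mem_pos)
    act = frame.fil_active
    beads = frame.fil_beads[act]
    fil_pos = beads.reshape(-1, 3)
    fil_species = np.tile(["O", "C", "I"], len(beads))
    pos = np.vstack([frame.mem_pos, fil_pos])
    species = np.concatenate([np.full(mem_n, "M"), fil_species])
    normals = np.vstack([frame.mem_nrm, np.zeros_like(fil_pos)])
    with open(path, mode) as fh:
        write_extxyz_frame(fh, pos, species, normals, time=frame.time)


def read_extxyz(path: str | Path) -> list[dict]:
    """Read all frames of an extended-XYZ file written by this module.

    Returns a list of dicts with 'species', 'pos', and (if present)
    'normal' and 'time'.
    """
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            header = fh.readline()
            time = None
            for tok in header.split():
                if tok.startswith("Time="):
                    time = float(tok[5:])
            has_normals = "normal:R:3" in header
            species = []
            pos = np.empty((n, 3))
            nrm = np.empty((n, 3)) if has_normals else None
            for k in range(n):
                parts = fh.readline().split()
                species.append(parts[0])
                pos[k] = [float(v) for v in parts[1:4]]
                if has_normals:
                    nrm[k] = [float(v) for v in parts[4:7]]
            frame = {"species": species, "pos": pos, "time": time}
            if has_normals:
                frame["normal"] = nrm
            frames.append(frame)
    return frames


def write_outcome(path: str | Path, outcome, schedule=None) -> None:
    """Write a DivisionOutcome (plus its schedule) as JSON."""
    import dataclasses
    data = dataclasses.asdict(outcome)
    if schedule is not None:
        data["schedule"] = dataclasses.asdict(schedule)
    Path(path).write_text(json.dumps(data, indent=2, default=float))


def save_checkpoint(path: str | Path, sim) -> None:
    """Full restart file: simulation state including the RNG state."""
    st = sim.state
    rng_state = json.dumps(st.rng.bit_generator.state)
    np.savez(
        path,
        time=st.time, step=st.step,
        mem_pos=st.mem_pos, mem_nrm=st.mem_nrm,
        mem_vel=st.mem_vel, mem_ang=st.mem_ang,
        sub_com=st.sub_com, sub_quat=st.sub_quat,
        sub_vel=st.sub_vel, sub_ang=st.sub_ang,
        active=st.active, rest=st.rest, transitioned=st.transitioned,
        removed_side=st.removed_side, removal_pos=st.removal_pos,
        protocol_steps=st.protocol_steps,
        disassembly_steps=st.disassembly_steps,
        fully_disassembled=st.fully_disassembled,
        n_transitioned=sim.n_transitioned,
        rng_state=np.frombuffer(rng_state.encode(), dtype=np.uint8),
        # pair-list state: restoring it verbatim keeps the floating-point
        # summation order identical, so replay is bitwise exact
        mm_pairs=sim._mm_pairs[:sim._pair_counts[0]],
        ad_pairs=sim._ad_pairs[:sim._pair_counts[1]],
        rep_pairs=sim._rep_pairs[:sim._pair_counts[2]],
        pair_ref=sim._pair_ref,
        pos_buf=sim._pos_buf,
    )


def load_checkpoint(path: str | Path, sim) -> None:
    """Restore a simulation in place from :func:`save_checkpoint`."""
    with np.load(path) as data:
        st = sim.state
        st.time = float(data["time"])
        st.step = int(data["step"])
        for name in ("mem_pos", "mem_nrm", "mem_vel", "mem_ang", "sub_com",
                     "sub_quat", "sub_vel", "sub_ang", "rest",
                     "removal_pos"):
            getattr(st, name)[:] = data[name]
        st.active[:] = data["active"]
        st.transitioned[:] = data["transitioned"]
        st.removed_side[:] = data["removed_side"]
        st.protocol_steps = int(data["protocol_steps"])
        st.disassembly_steps = int(data["disassembly_steps"])
        st.fully_disassembled = bool(data["fully_disassembled"])
        sim._n_transitioned = int(data["n_transitioned"])
        rng_state = json.loads(bytes(data["rng_state"]).decode())
        st.rng.bit_generator.state = rng_state
        # rebuild per-particle alive flags from the active range
        sim.alive[:sim.n_mem] = True
        for s in range(sim.n_sub):
            sim.alive[sim.n_mem + 3 * s:sim.n_mem + 3 * s + 3] = st.active[s]
        for name, arr in (("_mm_pairs", data["mm_pairs"]),
                          ("_ad_pairs", data["ad_pairs"]),
                          ("_rep_pairs", data["rep_pairs"])):
            buf = getattr(sim, name)
            if len(arr) > buf.shape[0]:
                buf = np.empty((len(arr), 2), dtype=np.int64)
                setattr(sim, name, buf)
            buf[:len(arr)] = arr
        sim._pair_counts[:] = [len(data["mm_pairs"]), len(data["ad_pairs"]),
                               len(data["rep_pairs"])]
        sim._pair_ref[:] = data["pair_ref"]
        sim._pos_buf[:] = data["pos_buf"]
        sim.energies = sim._compute_forces()
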