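"""Standard-format input/output.

Text formats: LAMMPS data (initial states with bonds and angles), LAMMPS
dump (trajectories; ``id mol type x y z ix iy iz``, type 1 = cold, 2 =
hot), XYZ, and tab-separated observable series.  Binary container: HDF5
with layout ``/positions [frame, monomer, 3]`` (unwrapped), ``/velocities``,
``/time``, ``/box``, ``/labels``, ``/closed`` and the config hash, seed and
parameter YAML as attributes.  Every writer embeds the parameter hash so
mixed-provenance files are detected downstream.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigMismatchError
from .params import ModelParameters
from .state import MeltState, Trajectory

__all__ = [
    "write_lammps_data",
    "read_lammps_data",
    "write_lammps_dump",
    "read_lammps_dump",
    "write_xyz",
    "read_xyz",
    "write_trajectory_h5",
    "read_trajectory_h5",
]


# --------------------------------------------------------------------------
# LAMMPS data
# --------------------------------------------------------------------------


def write_lammps_data(state: MeltState, path, config_hash=None):
    p = state.params
    bonds = state.bonds()
    angles = state.angles()
    img = state.image_flags()
    wrapped = state.positions - img * state.box
    mol = np.repeat(np.arange(1, state.M + 1), state.N)
    types = np.where(state.hot, 2, 1)
    tag = config_hash or p.content_hash()
    with open(path, "w") as fh:
        fh.write(f"ringmelt data file | config {tag} | time {state.time:.6f}\n\n")
        fh.write(f"{p.n_monomers} atoms\n{len(bonds)} bonds\n{len(angles)} angles\n\n")
        fh.write("2 atom types\n1 bond types\n1 angle types\n\n")
        for d, ax in enumerate("xyz"):
            fh.write(f"0.0 {state.box[d]:.10f} {ax}lo {ax}hi\n")
        fh.write("\nMasses\n\n")
        fh.write(f"1 {p.mass}\n2 {p.mass}\n")
        fh.write("\nAtoms # molecular\n\n")
        for i in range(p.n_monomers):
            fh.write(
                f"{i + 1} {mol[i]} {types[i]} "
                f"{wrapped[i, 0]:.10f} {wrapped[i, 1]:.10f} {wrapped[i, 2]:.10f} "
                f"{img[i, 0]} {img[i, 1]} {img[i, 2]}\n"
            )
        fh.write("\nVelocities\n\n")
        for i in range(p.n_monomers):
            v = state.velocities[i]
            fh.write(f"{i + 1} {v[0]:.10f} {v[1]:.10f} {v[2]:.10f}\n")
        fh.write("\nBonds\n\n")
        for k, (a, b) in enumerate(bonds):
            fh.write(f"{k + 1} 1 {a + 1} {b + 1}\n")
        fh.write("\nAngles\n\n")
        for k, (a, b, c) in enumerate(angles):
            fh.write(f"{k + 1} 1 {a + 1} {b + 1} {c + 1}\n")


def read_lammps_data(path, params: ModelParameters, expect_hash=None) -> MeltState:
    """Read a state written by :func:`write_lammps_data`.

    ``params`` supplies the model constants (the data file stores geometry
    and topology); ring closure is reconstructed from the bond list.
    """
    with open(path) as fh:
        lines = fh.readlines()
    header = lines[0]
    file_hash = None
    if "config" in header:
        file_hash = header.split("config")[1].split("|")[0].strip()
    if expect_hash is not None and file_hash != expect_hash:
        raise ConfigMismatchError(
            f"data file was written under config {file_hash}, expected {expect_hash}"
        )
    time = 0.0
    if "time" in header:
        time = float(header.split("time")[1].strip())
    box = np.zeros(3)
    section = None
    atoms, vels, bond_pairs = {}, {}, []
    for raw in lines[1:]:
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if line.endswith(("xlo xhi", "ylo yhi", "zlo zhi")):
            parts = line.split()
            box["xyz".index(parts[2][0])] = float(parts[1]) - float(parts[0])
            continue
        if line in ("Masses", "Atoms", "Velocities", "Bonds", "Angles"):
            section = line
            continue
        parts = line.split()
        if section == "Atoms" and len(parts) >= 6:
            i = int(parts[0]) - 1
            x = np.array(parts[3:6], dtype=float)
            img = (
                np.array(parts[6:9], dtype=int) if len(parts) >= 9 else np.zeros(3)
            )
            atoms[i] = (int(parts[2]), x, img)
        elif section == "Velocities" and len(parts) == 4:
            vels[int(parts[0]) - 1] = np.array(parts[1:], dtype=float)
        elif section == "Bonds" and len(parts) == 4:
            bond_pairs.append((int(parts[2]) - 1, int(parts[3]) - 1))
    n = params.n_monomers
    if len(atoms) != n:
        raise ValueError(f"expected {n} atoms, file has {len(atoms)}")
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    hot = np.zeros(n, dtype=bool)
    for i, (t, x, img) in atoms.items():
        pos[i] = x + img * box
        hot[i] = t == 2
    for i, v in vels.items():
        vel[i] = v
    bond_set = set(map(tuple, map(sorted, bond_pairs)))
    closed = np.array(
        [
            tuple(sorted((r * params.N, (r + 1) * params.N - 1))) in bond_set
            for r in range(params.M)
        ]
    )
    state = MeltState(
        positions=pos,
        velocities=vel,
        box=box,
        hot=hot,
        closed=closed,
        params=params,
        time=time,
    )
    return state


# --------------------------------------------------------------------------
# LAMMPS dump
# --------------------------------------------------------------------------


def write_lammps_dump(traj: Trajectory, path, config_hash=None):
    p = traj.params
    mol = np.repeat(np.arange(1, traj.M + 1), traj.N)
    types = np.where(traj.hot, 2, 1)
    tag = config_hash or p.content_hash()
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            step = int(round(traj.times[k] / p.dt))
            pos = traj.positions[k]
            img = np.floor(pos / traj.box).astype(int)
            wrapped = pos - img * traj.box
            fh.write("ITEM: TIMESTEP\n")
            fh.write(f"{step}\n")
            fh.write("ITEM: NUMBER OF ATOMS\n")
            fh.write(f"{p.n_monomers}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {traj.box[d]:.10f}\n")
            fh.write(f"ITEM: ATOMS id mol type x y z ix iy iz # config {tag}\n")
            for i in range(p.n_monomers):
                fh.write(
                    f"{i + 1} {mol[i]} {types[i]} "
                    f"{wrapped[i, 0]:.8f} {wrapped[i, 1]:.8f} {wrapped[i, 2]:.8f} "
                    f"{img[i, 0]} {img[i, 1]} {img[i, 2]}\n"
                )


def read_lammps_dump(path, params: ModelParameters, expect_hash=None) -> Trajectory:
    frames, times = [], []
    box = np.zeros(3)
    hot = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    file_hash = None
    while i < len(lines):
        if lines[i].startswith("ITEM: TIMESTEP"):
            step = int(lines[i + 1])
            i += 2
        elif lines[i].startswith("ITEM: NUMBER OF ATOMS"):
            n = int(lines[i + 1])
            i += 2
        elif lines[i].startswith("ITEM: BOX BOUNDS"):
            for d in range(3):
                lo, hi = map(float, lines[i + 1 + d].split())
                box[d] = hi - lo
            i += 4
        elif lines[i].startswith("ITEM: ATOMS"):
            if "config" in lines[i]:
                file_hash = lines[i].split("config")[1].strip()
            pos = np.empty((n, 3))
            hot = np.zeros(n, dtype=bool)
            for k in range(n):
                parts = lines[i + 1 + k].split()
                idx = int(parts[0]) - 1
                hot[idx] = int(parts[2]) == 2
                x = np.array(parts[3:6], dtype=float)
                img = np.array(parts[6:9], dtype=int)
                pos[idx] = x + img * box
            frames.append(pos)
            times.append(step * params.dt)
            i += 1 + n
        else:
            i += 1
    if expect_hash is not None and file_hash != expect_hash:
        raise ConfigMismatchError(
            f"dump written under config {file_hash}, expected {expect_hash}"
        )
    return Trajectory(
        times=np.array(times),
        positions=np.array(frames),
        box=box,
        hot=hot,
        closed=np.ones(params.M, dtype=bool),
        params=params,
        meta={"source": str(path), "config_hash": file_hash},
    )


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------


def write_xyz(state: MeltState, path, config_hash=None):
    """XYZ snapshot with unwrapped coordinates; element C = cold, H = hot."""
    tag = config_hash or state.params.content_hash()
    with open(path, "w") as fh:
        fh.write(f"{state.params.n_monomers}\n")
        fh.write(
            f"time={state.time:.6f} box={state.box[0]:.6f},"
            f"{state.box[1]:.6f},{state.box[2]:.6f} config={tag}\n"
        )
        for i in range(state.params.n_monomers):
            el = "H" if state.hot[i] else "C"
            x = state.positions[i]
            fh.write(f"{el} {x[0]:.8f} {x[1]:.8f} {x[2]:.8f}\n")


def read_xyz(path, params: ModelParameters) -> MeltState:
    with open(path) as fh:
        n = int(fh.readline())
        comment = fh.readline()
        pos = np.empty((n, 3))
        hot = np.zeros(n, dtype=bool)
        for i in range(n):
            parts = fh.readline().split()
            hot[i] = parts[0] == "H"
            pos[i] = [float(v) for v in parts[1:4]]
    time = 0.0
    box = np.full(3, params.box_edge)
    for token in comment.split():
        if token.startswith("time="):
            time = float(token[5:])
        elif token.startswith("box="):
            box = np.array(token[4:].split(","), dtype=float)
    return MeltState(
        positions=pos,
        velocities=np.zeros((n, 3)),
        box=box,
        hot=hot,
        closed=np.ones(params.M, dtype=bool),
        params=params,
        time=time,
    )


# --------------------------------------------------------------------------
# HDF5
# --------------------------------------------------------------------------


def write_trajectory_h5(traj: Trajectory, path, config_hash=None):
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("positions", data=traj.positions)
        if traj.velocities is not None:
            f.create_dataset("velocities", data=traj.velocities)
        f.create_dataset("time", data=traj.times)
        f.create_dataset("box", data=traj.box)
        f.create_dataset("labels", data=traj.hot.astype(np.int8))
        f.create_dataset("closed", data=traj.closed.astype(np.int8))
        f.attrs["config_hash"] = config_hash or traj.params.content_hash()
        f.attrs["params_yaml"] = traj.params.to_yaml()
        f.attrs["seed"] = int(traj.meta.get("seed", -1))


def read_trajectory_h5(path, expect_hash=None) -> Trajectory:
    import h5py

    with h5py.File(path, "r") as f:
        params = ModelParameters.from_yaml(f.attrs["params_yaml"])
        file_hash = f.attrs["config_hash"]
        if expect_hash is not None and file_hash != expect_hash:
            raise ConfigMismatchError(
                f"trajectory written under config {file_hash}, expected {expect_hash}"
            )
        traj = Trajectory(
            times=f["time"][:],
            positions=f["positions"][:],
            velocities=f["velocities"][:] if "velocities" in f else None,
            box=f["box"][:],
            hot=f["labels"][:].astype(bool),
            closed=f["closed"][:].astype(bool),
            params=params,
            meta={"seed": int(f.attrs["seed"]), "config_hash": str(file_hash)},
        )
    return traj
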