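"""Time propagation: velocity-Verlet NVE dynamics with per-group velocity
rescaling during equilibration, fixed-atom constraints, an optional constant
center-of-mass drive (the kinematic surrogate for field-driven
translocation), seeded initial-state randomization, and trajectory
recording.

Sampling is strictly NVE (thermostat off) so velocity autocorrelations are
not contaminated by thermostat coupling.  Runs are bit-reproducible for a
fixed seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import MolecularSystem
from .units import APS_TO_AFS, FORCE_TO_ACC, KB


class SimulationError(RuntimeError):
    pass


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Kinetic energy in kcal/mol for velocities in Å/fs."""
    return float(0.5 * np.sum(masses[:, None] * velocities**2) / FORCE_TO_ACC)


def instantaneous_temperature(masses, velocities) -> float:
    """Kinetic temperature (K), 3N degrees of freedom."""
    n = len(masses)
    if n == 0:
        raise ValueError("empty atom selection")
    return 2.0 * kinetic_energy(masses, velocities) / (3.0 * n * KB)


@dataclass
class SimulationConfig:
    """Run parameters.

    dt in fs; temperatures is a per-group mapping in K used both for the
    initial Maxwell–Boltzmann draw and for equilibration rescaling;
    com_velocity optionally pins a named group's center-of-mass velocity
    (Å/ps) throughout sampling.
    """

    dt: float = 0.05
    n_steps: int = 32768
    record_stride: int = 1
    temperatures: dict = field(default_factory=dict)   # group -> K
    com_velocity: tuple | None = None                  # (group, (vx,vy,vz) Å/ps)
    seed: int = 0
    equilibration_steps: int = 0
    thermostat_interval: int = 10
    record_positions: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if any(t < 0 for t in self.temperatures.values()):
            raise ValueError("temperatures must be >= 0")


@dataclass
class Trajectory:
    """Recorded per-step velocities (and positions) at fixed time spacing."""

    dt: float                      # fs between recorded frames
    atom_indices: np.ndarray       # selection, indices into the source system
    velocities: np.ndarray         # (n_rec, n_sel, 3) Å/fs
    positions: np.ndarray          # (n_rec, n_sel, 3) Å (may be empty)
    groups: dict = field(default_factory=dict)
    elements: list = field(default_factory=list)
    final_system: "MolecularSystem | None" = None

    @property
    def n_records(self) -> int:
        return self.velocities.shape[0]

    def _col(self, atom: int) -> int:
        pos = np.nonzero(self.atom_indices == atom)[0]
        if len(pos) == 0:
            raise KeyError(f"atom {atom} not recorded in trajectory")
        return int(pos[0])

    def velocity_of(self, atom: int) -> np.ndarray:
        """(n_rec, 3) velocity series of one atom (source-system index)."""
        return self.velocities[:, self._col(atom), :]

    def position_of(self, atom: int) -> np.ndarray:
        if self.positions.size == 0:
            raise ValueError("positions were not recorded")
        return self.positions[:, self._col(atom), :]


# ---------------------------------------------------------------------------
# elementary operations

def init_velocities(system: MolecularSystem, temperatures: dict, seed: int = 0,
                    ) -> MolecularSystem:
    """Maxwell–Boltzmann draw per group at its temperature.

    Group net momentum is removed and velocities rescaled so each group's
    instantaneous kinetic temperature matches the target exactly.  Fixed
    atoms stay at rest.
    """
    rng = np.random.default_rng(seed)
    out = system.copy()
    for gname in sorted(out.groups):
        T = temperatures.get(gname, 0.0)
        idx = out.groups[gname]
        idx = idx[~out.fixed_mask[idx]]
        if len(idx) == 0:
            continue
        if T <= 0:
            out.velocities[idx] = 0.0
            continue
        m = out.masses[idx]
        sigma = np.sqrt(KB * T * FORCE_TO_ACC / m)
        v = rng.standard_normal((len(idx), 3)) * sigma[:, None]
        v -= np.average(v, axis=0, weights=m)          # remove net momentum
        t_now = instantaneous_temperature(m, v)
        v *= np.sqrt(T / t_now)
        out.velocities[idx] = v
    out.velocities[out.fixed_mask] = 0.0
    return out


def velocity_verlet_step(system: MolecularSystem, forces_fn, dt: float,
                         forces: np.ndarray | None = None):
    """One velocity-Verlet update; returns (system, forces_at_new_positions).

    Fixed atoms are not moved and keep zero velocity.  ``forces_fn`` maps
    positions to (energy, forces).
    """
    out = system.copy()
    if forces is None:
        _, forces = forces_fn(out.positions)
    _step_inplace(out, forces_fn, dt, forces)
    return out, forces


def _step_inplace(sys: MolecularSystem, forces_fn, dt: float, forces: np.ndarray):
    """In-place velocity-Verlet kick-drift-kick; mutates sys, returns new forces."""
    mobile = ~sys.fixed_mask
    acc = forces * (FORCE_TO_ACC / sys.masses[:, None])
    if not np.all(np.isfinite(acc[mobile])):
        bad = int(np.nonzero(~np.isfinite(acc).all(axis=1) & mobile)[0][0])
        raise SimulationError(f"non-finite force on atom {bad}")
    sys.velocities[mobile] += 0.5 * dt * acc[mobile]
    sys.positions[mobile] += dt * sys.velocities[mobile]
    _, new_forces = forces_fn(sys.positions)
    acc = new_forces * (FORCE_TO_ACC / sys.masses[:, None])
    sys.velocities[mobile] += 0.5 * dt * acc[mobile]
    sys.velocities[sys.fixed_mask] = 0.0
    return new_forces


def rescale_thermostat(system: MolecularSystem, group: str, t_target: float,
                       ) -> MolecularSystem:
    """Scale group velocities by sqrt(T_target / T_current)."""
    out = system.copy()
    _rescale_inplace(out, group, t_target)
    return out


def _rescale_inplace(sys: MolecularSystem, group: str, t_target: float):
    idx = sys.group_indices(group)
    idx = idx[~sys.fixed_mask[idx]]
    if len(idx) == 0:
        raise ValueError(f"group {group!r} has no mobile atoms")
    t_now = instantaneous_temperature(sys.masses[idx], sys.velocities[idx])
    if t_now <= 0:
        raise ValueError(f"group {group!r} has zero kinetic energy; cannot rescale")
    sys.velocities[idx] *= np.sqrt(t_target / t_now)


def drive_com_velocity(system: MolecularSystem, group: str, v_aps,
                       ) -> MolecularSystem:
    """Reset the group's center-of-mass velocity to ``v_aps`` (Å/ps).

    Internal (thermal) velocities are preserved: the difference between the
    target and current c.o.m. velocity is added uniformly to every atom of
    the group.
    """
    out = system.copy()
    _drive_inplace(out, group, np.asarray(v_aps, dtype=float) * APS_TO_AFS)
    return out


def _drive_inplace(sys: MolecularSystem, group: str, v_afs: np.ndarray):
    idx = sys.group_indices(group)
    if len(idx) == 0:
        raise ValueError(f"group {group!r} is empty")
    m = sys.masses[idx]
    v_com = np.average(sys.velocities[idx], axis=0, weights=m)
    sys.velocities[idx] += v_afs - v_com


def randomize_initial_state(system: MolecularSystem, fraction: float,
                            seed: int = 0, group: str = "nucleotide",
                            ) -> MolecularSystem:
    """Seeded multiplicative perturbation of the molecule's initial state.

    Displacements from the group center of mass and velocities are scaled
    component-wise by (1 + u) with u uniform in [-fraction, fraction],
    emulating run-to-run randomization of starting conditions.
    """
    if not 0.0 <= fraction <= 0.5:
        raise ValueError("fraction must be in [0, 0.5]")
    out = system.copy()
    if fraction == 0.0:
        return out
    rng = np.random.default_rng(seed)
    idx = out.group_indices(group)
    com = np.average(out.positions[idx], axis=0, weights=out.masses[idx])
    scale = 1.0 + rng.uniform(-fraction, fraction, size=(len(idx), 3))
    out.positions[idx] = com + (out.positions[idx] - com) * scale
    out.velocities[idx] *= 1.0 + rng.uniform(-fraction, fraction, size=(len(idx), 3))
    return out


# ---------------------------------------------------------------------------
# full run

def run_simulation(system: MolecularSystem, config: SimulationConfig, forces_fn,
                   record_atoms: np.ndarray | None = None) -> Trajectory:
    """Equilibrate (velocity rescaling on), then sample NVE.

    During sampling the thermostat is off; if ``config.com_velocity`` names
    a group, its c.o.m. velocity is re-pinned every step.  Velocities (and
    positions) of ``record_atoms`` (default: all) are recorded every
    ``record_stride`` steps; the number of records is
    ``n_steps // record_stride``.
    """
    sys = system.copy()
    if config.temperatures and not np.any(np.abs(sys.velocities) > 0):
        sys = init_velocities(sys, config.temperatures, seed=config.seed)
    if record_atoms is None:
        record_atoms = np.arange(sys.n_atoms)
    record_atoms = np.asarray(record_atoms, dtype=int)

    _, forces = forces_fn(sys.positions)

    # equilibration: thermostat on
    for step in range(config.equilibration_steps):
        forces = _step_inplace(sys, forces_fn, config.dt, forces)
        if (step + 1) % config.thermostat_interval == 0:
            for gname, T in config.temperatures.items():
                if T > 0 and gname in sys.groups:
                    _rescale_inplace(sys, gname, T)

    drive = None
    if config.com_velocity is not None:
        gname, vec = config.com_velocity
        drive = (gname, np.asarray(vec, dtype=float) * APS_TO_AFS)
        _drive_inplace(sys, *drive)

    n_rec = config.n_steps // config.record_stride
    vel_rec = np.zeros((n_rec, len(record_atoms), 3))
    pos_rec = np.zeros((n_rec, len(record_atoms), 3)) if config.record_positions \
        else np.zeros((0, 0, 3))

    e0, _ = forces_fn(sys.positions)
    e_scale = max(abs(e0 + kinetic_energy(sys.masses, sys.velocities)), 1.0)
    rec = 0
    for step in range(config.n_steps):
        forces = _step_inplace(sys, forces_fn, config.dt, forces)
        if drive is not None:
            _drive_inplace(sys, *drive)
        if (step + 1) % config.record_stride == 0:
            vel_rec[rec] = sys.velocities[record_atoms]
            if config.record_positions:
                pos_rec[rec] = sys.positions[record_atoms]
            rec += 1
        if (step + 1) % 512 == 0:
            e, _ = forces_fn(sys.positions)
            etot = e + kinetic_energy(sys.masses, sys.velocities)
            if abs(etot) > 10.0 * e_scale:
                raise SimulationError(
                    f"energy divergence at step {step + 1}: |E| = {abs(etot):.3g} "
                    f"exceeds 10x initial {e_scale:.3g}")

    traj = Trajectory(
        dt=config.dt * config.record_stride,
        atom_indices=record_atoms,
        velocities=vel_rec,
        positions=pos_rec,
        groups={k: v.copy() for k, v in sys.groups.items()},
        elements=[sys.elements[i] for i in record_atoms],
        final_system=sys,
    )
    return traj


# ---------------------------------------------------------------------------
# trajectory file IO (velocity dump)

def save_trajectory(path, traj: Trajectory, meta: dict | None = None) -> None:
    """Write a velocity dump: HDF5 (``.h5``) or plain columnar text.

    The text layout is one frame block per record: a ``# frame`` line, then
    ``atom vx vy vz [x y z]`` rows; dt and provenance go in the header.
    """
    path = str(path)
    meta = dict(meta or {})
    if path.endswith(".h5") or path.endswith(".hdf5"):
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["dt_fs"] = traj.dt
            for k, v in meta.items():
                f.attrs[k] = v
            f.create_dataset("atom_indices", data=traj.atom_indices)
            f.create_dataset("velocities", data=traj.velocities)
            if traj.positions.size:
                f.create_dataset("positions", data=traj.positions)
            f.create_dataset("elements", data=np.array(traj.elements, dtype="S4"))
            for gname, idx in traj.groups.items():
                f.create_dataset(f"groups/{gname}", data=idx)
        return
    with open(path, "w") as f:
        f.write(f"# sersmd velocity dump | dt_fs = {traj.dt!r}\n")
        for k, v in meta.items():
            f.write(f"# {k}: {v}\n")
        f.write(f"# atoms: {' '.join(str(int(i)) for i in traj.atom_indices)}\n")
        f.write(f"# elements: {' '.join(traj.elements)}\n")
        for gname, idx in traj.groups.items():
            f.write(f"# group {gname}: {' '.join(str(int(i)) for i in idx)}\n")
        has_pos = traj.positions.size > 0
        f.write("# columns: atom vx vy vz" + (" x y z" if has_pos else "") + "\n")
        for rec in range(traj.n_records):
            f.write(f"# frame {rec}\n")
            for col, atom in enumerate(traj.atom_indices):
                row = f"{int(atom)} " + " ".join(
                    f"{v:.12e}" for v in traj.velocities[rec, col])
                if has_pos:
                    row += " " + " ".join(f"{v:.12e}" for v in traj.positions[rec, col])
                f.write(row + "\n")


def load_trajectory(path) -> Trajectory:
    path = str(path)
    if path.endswith(".h5") or path.endswith(".hdf5"):
        import h5py
        with h5py.File(path, "r") as f:
            return Trajectory(
                dt=float(f.attrs["dt_fs"]),
                atom_indices=f["atom_indices"][...],
                velocities=f["velocities"][...],
                positions=f["positions"][...] if "positions" in f
                else np.zeros((0, 0, 3)),
                groups={k: f[f"groups/{k}"][...] for k in f.get("groups", {})},
                elements=[e.decode() for e in f["elements"][...]],
            )
    dt = None
    atoms: list[int] = []
    elements: list[str] = []
    groups: dict = {}
    vel_frames: list[list] = []
    pos_frames: list[list] = []
    has_pos = False
    with open(path) as f:
        for line in f:
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sersmd velocity dump"):
                    dt = float(body.split("=")[1])
                elif body.startswith("atoms:"):
                    atoms = [int(t) for t in body.split(":")[1].split()]
                elif body.startswith("elements:"):
                    elements = body.split(":")[1].split()
                elif body.startswith("group "):
                    name, _, idx = body[6:].partition(":")
                    groups[name.strip()] = np.array(idx.split(), dtype=int)
                elif body.startswith("columns:"):
                    has_pos = " x y z" in body
                elif body.startswith("frame"):
                    vel_frames.append([])
                    pos_frames.append([])
                continue
            parts = line.split()
            vel_frames[-1].append([float(v) for v in parts[1:4]])
            if has_pos:
                pos_frames[-1].append([float(v) for v in parts[4:7]])
    if dt is None:
        raise ValueError(f"{path}: not a sersmd velocity dump")
    return Trajectory(
        dt=dt,
        atom_indices=np.asarray(atoms, dtype=int),
        velocities=np.asarray(vel_frames, dtype=float).reshape(len(vel_frames),
                                                               len(atoms), 3),
        positions=np.asarray(pos_frames, dtype=float).reshape(len(pos_frames),
                                                              len(atoms), 3)
        if has_pos else np.zeros((0, 0, 3)),
        groups=groups,
        elements=elements,
    )
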