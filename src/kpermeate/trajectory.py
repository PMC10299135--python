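"""In-memory trajectory model and I/O.

The canonical container is :class:`Trajectory`: a fixed particle table
(:class:`Particles`) plus dense ``(n_frames, n_particles, 3)`` position
(and optionally velocity) arrays on a uniform time grid.  Units are
Angstrom / picosecond / THz throughout; readers for nm-based formats
convert on ingest.  The pore axis is a unit vector, by convention ``+z``
with the extracellular side at larger ``z``.

Two input routes exist:

* a plain columnar text dialect (CSV, one row per frame/particle pair)
  that round-trips exactly and needs no binary dependencies, and
* standard MD formats (GRO/PDB structure with XTC/TRR/PDB coordinates)
  read through MDAnalysis behind :func:`read_trajectory`.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ParticleLookupError

__all__ = [
    "Species",
    "Particles",
    "ParticleRecord",
    "TrajectoryFrame",
    "Trajectory",
    "read_columnar",
    "write_columnar",
    "read_trajectory",
    "project_axial",
]

#: Tolerance on frame-time uniformity, ps.
DT_TOL = 1e-9

COLUMNAR_COLUMNS = [
    "frame", "time_ps", "particle_id", "species",
    "residue", "atom", "chain", "x", "y", "z",
]
VELOCITY_COLUMNS = ["vx", "vy", "vz"]


class Species(str, enum.Enum):
    """Particle species relevant to selectivity-filter analysis."""

    K = "K"
    WATER_O = "WATER_O"
    WATER_H = "WATER_H"
    PROTEIN_REF = "PROTEIN_REF"
    OTHER = "OTHER"


@dataclass(frozen=True)
class Particles:
    """Static per-particle metadata, parallel arrays of length ``n``.

    ``ids`` are stable across frames and unique; ``species`` holds the
    string values of :class:`Species`.
    """

    ids: np.ndarray
    species: np.ndarray
    residue_label: np.ndarray
    atom_label: np.ndarray
    chain_id: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        for name in ("species", "residue_label", "atom_label", "chain_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"particle field {name!r} has wrong length")
        if len(np.unique(self.ids)) != n:
            raise ValueError("particle ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def empty(cls) -> "Particles":
        s = np.array([], dtype=object)
        return cls(np.array([], dtype=np.int64), s.copy(), s.copy(), s.copy(), s.copy())

    @classmethod
    def build(cls, rows: Sequence[tuple]) -> "Particles":
        """Build from ``(id, species, residue, atom, chain)`` tuples."""
        if not rows:
            return cls.empty()
        ids, sp, res, atom, chain = zip(*rows)
        to_obj = lambda seq: np.array([str(x) for x in seq], dtype=object)
        return cls(np.asarray(ids, dtype=np.int64), to_obj(sp),
                   to_obj(res), to_obj(atom), to_obj(chain))

    def mask(self, species: Species | str) -> np.ndarray:
        """Boolean mask of particles of one species."""
        value = species.value if isinstance(species, Species) else str(species)
        return self.species == value

    def index_of(self, particle_id: int) -> int:
        idx = np.flatnonzero(self.ids == particle_id)
        if idx.size == 0:
            raise ParticleLookupError(f"unknown particle id {particle_id}")
        return int(idx[0])


@dataclass(frozen=True)
class ParticleRecord:
    """One particle in one frame (a convenience view, not the storage)."""

    particle_id: int
    species: str
    residue_label: str
    atom_label: str
    chain_id: str
    position: np.ndarray
    velocity: Optional[np.ndarray] = None


@dataclass(frozen=True)
class TrajectoryFrame:
    """Zero-copy view of a single frame of a :class:`Trajectory`."""

    index: int
    time: float
    particles: Particles
    positions: np.ndarray
    velocities: Optional[np.ndarray]
    axis: np.ndarray

    @property
    def records(self) -> Iterator[ParticleRecord]:
        for i in range(len(self.particles)):
            vel = None if self.velocities is None else self.velocities[i]
            yield ParticleRecord(
                int(self.particles.ids[i]), str(self.particles.species[i]),
                str(self.particles.residue_label[i]), str(self.particles.atom_label[i]),
                str(self.particles.chain_id[i]), self.positions[i], vel,
            )

    def axial(self) -> np.ndarray:
        """Axial coordinate of every particle in this frame, Angstrom."""
        return self.positions @ self.axis


@dataclass
class Trajectory:
    """Uniformly sampled trajectory of a fixed particle set.

    Parameters
    ----------
    particles : Particles
        Static metadata; the id set is identical in every frame.
    times : ndarray, shape (F,)
        Frame times in ps, strictly increasing on a uniform grid.
    positions : ndarray, shape (F, N, 3)
        Cartesian positions, Angstrom.
    velocities : ndarray, shape (F, N, 3), optional
        Velocities, Angstrom/ps.
    axis : ndarray, shape (3,)
        Unit pore-axis vector; larger projections are extracellular.
    dt : float, optional
        Sampling interval, ps.  Inferred from ``times`` when two or more
        frames exist; required metadata otherwise only if you care.
    """

    particles: Particles
    times: np.ndarray
    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    dt: Optional[float] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (F, N, 3)")
        if self.positions.shape[0] != self.times.shape[0]:
            raise ValueError("positions and times disagree on frame count")
        if self.positions.shape[1] != len(self.particles):
            raise ValueError("positions and particle table disagree on particle count")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")
        norm = np.linalg.norm(self.axis)
        if not np.isclose(norm, 1.0, atol=1e-9):
            raise ValueError("axis must be a unit vector")
        if self.n_frames >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise FormatError("frame times must be strictly increasing")
            dt = float(steps[0])
            if np.any(np.abs(steps - dt) > DT_TOL):
                raise FormatError("frame times must lie on a uniform grid")
            if self.dt is None:
                self.dt = dt
            elif abs(self.dt - dt) > DT_TOL:
                raise FormatError("declared dt inconsistent with frame times")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Time spanned by the frames, ps (0 for fewer than 2 frames)."""
        return float(self.times[-1] - self.times[0]) if self.n_frames > 1 else 0.0

    def frame(self, index: int) -> TrajectoryFrame:
        vel = None if self.velocities is None else self.velocities[index]
        return TrajectoryFrame(index, float(self.times[index]), self.particles,
                               self.positions[index], vel, self.axis)

    def __iter__(self) -> Iterator[TrajectoryFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    def axial(self) -> np.ndarray:
        """Axial projections for every frame/particle, shape (F, N)."""
        return self.positions @ self.axis

    def time_reversed(self) -> "Trajectory":
        """The same path traversed backwards (frame times kept)."""
        vel = None if self.velocities is None else -self.velocities[::-1].copy()
        return Trajectory(self.particles, self.times.copy(),
                          self.positions[::-1].copy(), vel,
                          self.axis.copy(), self.dt, dict(self.metadata))


def project_axial(traj: Trajectory, particle_id: int) -> tuple[np.ndarray, np.ndarray]:
    """Axial coordinate of one particle over time.

    Returns ``(times_ps, z_angstrom)`` where ``z`` is the dot product of
    the position with the pore axis, one value per frame.
    """
    i = traj.particles.index_of(particle_id)
    return traj.times.copy(), traj.positions[:, i, :] @ traj.axis


# ---------------------------------------------------------------------------
# Columnar dialect


def write_columnar(traj: Trajectory, path: str | Path) -> Path:
    """Write the plain columnar dialect: one CSV row per (frame, particle).

    Velocity columns are present only when the trajectory carries
    velocities; an empty trajectory produces a header-only file.
    """
    path = Path(path)
    has_vel = traj.velocities is not None
    cols = COLUMNAR_COLUMNS + (VELOCITY_COLUMNS if has_vel else [])
    F, N = traj.n_frames, traj.n_particles
    data = {
        "frame": np.repeat(np.arange(F), N),
        "time_ps": np.repeat(traj.times, N),
        "particle_id": np.tile(traj.particles.ids, F),
        "species": np.tile(traj.particles.species, F),
        "residue": np.tile(traj.particles.residue_label, F),
        "atom": np.tile(traj.particles.atom_label, F),
        "chain": np.tile(traj.particles.chain_id, F),
    }
    flat = traj.positions.reshape(F * N, 3) if F * N else np.empty((0, 3))
    for k, c in enumerate(("x", "y", "z")):
        data[c] = flat[:, k]
    if has_vel:
        vflat = traj.velocities.reshape(F * N, 3) if F * N else np.empty((0, 3))
        for k, c in enumerate(VELOCITY_COLUMNS):
            data[c] = vflat[:, k]
    frame = pd.DataFrame(data, columns=cols)
    try:
        frame.to_csv(path, index=False, float_format="%.10g")
    except OSError as exc:
        raise OSError(f"cannot write columnar trajectory to {path}: {exc}") from exc
    return path


def read_columnar(path: str | Path | io.TextIOBase, axis: Optional[np.ndarray] = None) -> Trajectory:
    """Read the columnar dialect written by :func:`write_columnar`."""
    try:
        table = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"not a columnar trajectory file: {exc}") from exc
    missing = [c for c in COLUMNAR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"columnar file lacks required columns: {missing}")
    has_vel = all(c in table.columns for c in VELOCITY_COLUMNS)
    axis = np.array([0.0, 0.0, 1.0]) if axis is None else np.asarray(axis, dtype=float)

    if len(table) == 0:
        return Trajectory(Particles.empty(), np.empty(0), np.empty((0, 0, 3)),
                          velocities=np.empty((0, 0, 3)) if has_vel else None, axis=axis)

    frame_ids = np.unique(table["frame"].to_numpy())
    first = table[table["frame"] == frame_ids[0]].sort_values("particle_id")
    ids = first["particle_id"].to_numpy(dtype=np.int64)
    particles = Particles(
        ids,
        first["species"].to_numpy(dtype=object),
        first["residue"].astype(str).to_numpy(dtype=object),
        first["atom"].astype(str).to_numpy(dtype=object),
        first["chain"].astype(str).to_numpy(dtype=object),
    )
    n = len(ids)
    if len(table) != n * len(frame_ids):
        raise FormatError("every frame must contain the same particle set")

    table = table.sort_values(["frame", "particle_id"], kind="stable")
    if not np.array_equal(table["particle_id"].to_numpy().reshape(len(frame_ids), n),
                          np.tile(ids, (len(frame_ids), 1))):
        raise FormatError("particle id set varies across frames")
    times = table["time_ps"].to_numpy().reshape(len(frame_ids), n)[:, 0]
    pos = table[["x", "y", "z"]].to_numpy().reshape(len(frame_ids), n, 3)
    vel = (table[VELOCITY_COLUMNS].to_numpy().reshape(len(frame_ids), n, 3)
           if has_vel else None)
    return Trajectory(particles, times, pos, velocities=vel, axis=axis)


# ---------------------------------------------------------------------------
# Standard-format adapter (MDAnalysis)

_COLUMNAR_SUFFIXES = {".csv", ".txt", ".dat", ".traj"}


def read_trajectory(structure_path: Optional[str | Path],
                    coords_path: str | Path,
                    species_spec: Optional[Mapping[str, Species | str]] = None,
                    axis: Optional[np.ndarray] = None) -> Trajectory:
    """Read a trajectory from standard MD formats or the columnar dialect.

    ``species_spec`` maps MDAnalysis selection strings to species, e.g.
    ``{"name K POT": Species.K, "name OW OH2": Species.WATER_O}``.  It is
    ignored for columnar input, which carries species labels itself.
    A selection matching zero atoms raises :class:`ConfigurationError`
    naming the selector.  Positions are converted to Angstrom and
    velocities to Angstrom/ps on ingest.
    """
    coords_path = Path(coords_path)
    if coords_path.suffix.lower() in _COLUMNAR_SUFFIXES:
        return read_columnar(coords_path, axis=axis)
    if species_spec is None or not species_spec:
        raise ConfigurationError("species_spec is required for standard MD formats")
    return _read_mdanalysis(structure_path, coords_path, species_spec, axis)


def _read_mdanalysis(structure_path, coords_path, species_spec, axis) -> Trajectory:
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - installed in supported envs
        raise ImportError("MDAnalysis is required to read standard MD formats") from exc

    try:
        if structure_path is None:
            universe = mda.Universe(str(coords_path))
        else:
            universe = mda.Universe(str(structure_path), str(coords_path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read trajectory {coords_path}: {exc}") from exc

    index_list: list[int] = []
    rows: list[tuple] = []
    seen: set[int] = set()
    for selector, species in species_spec.items():
        group = universe.select_atoms(selector)
        if group.n_atoms == 0:
            raise ConfigurationError(f"selector {selector!r} matches no atoms")
        value = species.value if isinstance(species, Species) else str(species)
        for atom in group:
            if atom.ix in seen:
                continue
            seen.add(atom.ix)
            index_list.append(atom.ix)
            chain = getattr(atom, "segid", "") or getattr(atom, "chainID", "")
            rows.append((int(atom.ix), value,
                         f"{atom.resid}{atom.resname}", atom.name, chain))
    order = np.argsort([r[0] for r in rows])
    rows = [rows[i] for i in order]
    sel_idx = np.asarray(index_list)[order]
    particles = Particles.build(rows)

    times, pos, vel = [], [], []
    has_vel = True
    for ts in universe.trajectory:
        times.append(float(ts.time))
        pos.append(ts.positions[sel_idx].copy())
        if has_vel and getattr(ts, "has_velocities", False):
            vel.append(ts.velocities[sel_idx].copy())
        else:
            has_vel = False
    times_arr = np.asarray(times)
    if len(times_arr) >= 2 and np.any(np.diff(times_arr) <= 0):
        raise FormatError("frame times must be strictly increasing")
    # Single-frame readers sometimes report t=0 with dt unknown; that is fine.
    return Trajectory(particles, times_arr, np.asarray(pos),
                      velocities=np.asarray(vel) if has_vel and vel else None,
                      axis=np.array([0.0, 0.0, 1.0]) if axis is None else axis,
                      metadata={"source": str(coords_path)})
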