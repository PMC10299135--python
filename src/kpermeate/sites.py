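"""Selectivity-filter binding-site regions and per-frame assignment.

The filter of Kv1.2 is framed by six rings of oxygen atoms of the
conserved T-V-G-Y-G sequence.  Listed from the intracellular cavity
upward these are the 374THR side-chain hydroxyl oxygen, then the
backbone carbonyl oxygens of 374THR, 375VAL, 376GLY, 377TYR and 378GLY.
Each binding site is the axial slab between two successive rings
(S4 lowest, S0 highest); the cavity site S_cav extends 3 Angstrom
(0.3 nm) below the hydroxyl-oxygen ring.  Ring positions are the mean
axial coordinate over the four chains, so a single boundary per ring is
used, and intervals are half-open ``[lower, upper)`` with boundary hits
resolved to the upper site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .trajectory import Species, Trajectory, TrajectoryFrame

__all__ = [
    "SITE_NAMES", "LABEL_NAMES", "REFERENCE_ATOMS", "S_CAV_DEPTH",
    "SiteMap", "SiteAssignment", "build_site_map", "assign_sites",
    "pore_diameter",
]

#: Depth of the cavity site below the 374THR hydroxyl-oxygen ring, Angstrom.
S_CAV_DEPTH = 3.0

#: (residue, atom) pairs of the boundary oxygen rings, bottom to top.
REFERENCE_ATOMS = (
    ("374THR", "OG1"),   # side-chain hydroxyl oxygen
    ("374THR", "O"),
    ("375VAL", "O"),
    ("376GLY", "O"),
    ("377TYR", "O"),
    ("378GLY", "O"),
)

SITE_NAMES = ("S_cav", "S4", "S3", "S2", "S1", "S0")

#: Full label vocabulary; integer codes index this tuple.
LABEL_NAMES = ("OUTSIDE_BELOW",) + SITE_NAMES + ("OUTSIDE_ABOVE",)

OUTSIDE_BELOW = 0
S_CAV = 1
S0 = 6
OUTSIDE_ABOVE = 7
#: Codes of the five filter sites S4..S0.
FILTER_CODES = tuple(range(2, 7))
INSIDE_CODES = tuple(range(1, 7))  # S_cav..S0


@dataclass(frozen=True)
class SiteMap:
    """Ordered axial intervals for S_cav, S4..S0.

    ``edges`` holds the 7 boundaries from the bottom of S_cav up to the
    top of S0; site ``i`` (in :data:`SITE_NAMES` order) occupies
    ``[edges[i], edges[i+1])``.
    """

    edges: np.ndarray
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.shape != (7,):
            raise ValueError("a site map needs exactly 7 boundaries")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("site boundaries must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def lower(self) -> np.ndarray:
        return self.edges[:-1]

    @property
    def upper(self) -> np.ndarray:
        return self.edges[1:]

    def bounds(self, site: str) -> tuple[float, float]:
        i = SITE_NAMES.index(site)
        return float(self.edges[i]), float(self.edges[i + 1])

    def assign(self, z: np.ndarray) -> np.ndarray:
        """Label codes for axial coordinates (vectorised, half-open)."""
        return np.searchsorted(self.edges, np.asarray(z, dtype=float), side="right")

    def translated(self, offset: float) -> "SiteMap":
        return SiteMap(self.edges + offset, self.provenance)

    def to_frame(self) -> pd.DataFrame:
        prov = self.provenance if self.provenance else [""] * 6
        return pd.DataFrame({
            "site": SITE_NAMES,
            "lower_A": self.lower,
            "upper_A": self.upper,
            "provenance": list(prov),
        })

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.6f")
        return path


def build_site_map(frame: TrajectoryFrame) -> SiteMap:
    """Derive the site map from reference-oxygen positions in one frame.

    Each boundary is the mean axial coordinate of the matching oxygen
    ring across the (typically four) chains; the S_cav lower bound sits
    :data:`S_CAV_DEPTH` below the hydroxyl-oxygen ring.
    """
    z = frame.axial()
    is_ref = frame.particles.mask(Species.PROTEIN_REF)
    residues = frame.particles.residue_label
    atoms = frame.particles.atom_label

    ring_z = []
    provenance = []
    for residue, atom in REFERENCE_ATOMS:
        sel = is_ref & (residues == residue) & (atoms == atom)
        if not np.any(sel):
            raise ConfigurationError(
                f"missing reference atoms {atom!r} of residue {residue!r}")
        ring_z.append(float(np.mean(z[sel])))
        provenance.append(f"{residue}:{atom} mean of {int(sel.sum())} chains")
    edges = np.array([ring_z[0] - S_CAV_DEPTH] + ring_z)
    prov = (f"{REFERENCE_ATOMS[0][0]}:{REFERENCE_ATOMS[0][1]} - {S_CAV_DEPTH:g} A",
            *provenance[:-1])
    if np.any(np.diff(edges) <= 0):
        raise ConfigurationError("reference oxygen rings are not axially ordered")
    return SiteMap(edges, tuple(prov))


@dataclass
class SiteAssignment:
    """Per-frame site labels for the tracked species (K+ and water O).

    ``labels`` is an ``(n_frames, n_tracked)`` array of codes into
    :data:`LABEL_NAMES`.  The assignment is a partition: every tracked
    particle carries exactly one label per frame.
    """

    particle_ids: np.ndarray
    species: np.ndarray
    labels: np.ndarray
    times: np.ndarray
    dt: float
    site_map: SiteMap
    mode: str = "static"

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    @property
    def k_columns(self) -> np.ndarray:
        return np.flatnonzero(self.species == Species.K.value)

    @property
    def water_columns(self) -> np.ndarray:
        return np.flatnonzero(self.species == Species.WATER_O.value)

    def column_of(self, particle_id: int) -> int:
        idx = np.flatnonzero(self.particle_ids == particle_id)
        if idx.size == 0:
            raise KeyError(f"particle {particle_id} is not tracked")
        return int(idx[0])

    def label_series(self, particle_id: int) -> np.ndarray:
        return self.labels[:, self.column_of(particle_id)]

    def to_frame(self) -> pd.DataFrame:
        F, N = self.labels.shape
        names = np.asarray(LABEL_NAMES, dtype=object)
        return pd.DataFrame({
            "frame": np.repeat(np.arange(F), N),
            "time_ps": np.repeat(self.times, N),
            "particle_id": np.tile(self.particle_ids, F),
            "species": np.tile(self.species, F),
            "site": names[self.labels.reshape(-1)],
        })


def assign_sites(traj: Trajectory, site_map_mode: str = "static",
                 site_map: Optional[SiteMap] = None) -> SiteAssignment:
    """Assign every K+ ion and water oxygen to a site label per frame.

    ``site_map_mode``:

    * ``"static"`` (default): build the map from the first frame and use
      it throughout; matches the fixed dotted site lines of axial plots.
    * ``"per_frame"``: rebuild boundaries from each frame's reference
      atoms (supports a flexing filter).

    An explicit ``site_map`` overrides both modes.
    """
    if traj.n_frames == 0:
        raise ValueError("cannot assign sites on an empty trajectory")
    tracked = traj.particles.mask(Species.K) | traj.particles.mask(Species.WATER_O)
    cols = np.flatnonzero(tracked)
    z = traj.axial()[:, cols]

    if site_map is not None:
        the_map = site_map
        labels = the_map.assign(z)
        mode = "explicit"
    elif site_map_mode == "static":
        the_map = build_site_map(traj.frame(0))
        labels = the_map.assign(z)
        mode = "static"
    elif site_map_mode == "per_frame":
        labels = np.empty(z.shape, dtype=np.int64)
        the_map = build_site_map(traj.frame(0))
        for f in range(traj.n_frames):
            labels[f] = build_site_map(traj.frame(f)).assign(z[f])
        mode = "per_frame"
    else:
        raise ConfigurationError(f"unknown site_map_mode {site_map_mode!r}")

    dt = traj.dt if traj.dt is not None else 1.0
    return SiteAssignment(traj.particles.ids[cols].copy(),
                          traj.particles.species[cols].copy(),
                          labels.astype(np.uint8), traj.times.copy(),
                          float(dt), the_map, mode)


def pore_diameter(traj: Trajectory, residue: str) -> np.ndarray:
    """Carbonyl-oxygen cross distance of one filter residue, per frame.

    The tetramer has two diagonal (opposite-chain) carbonyl-oxygen
    pairs; the reported diameter is the mean of the two diagonal
    distances.  Requires the residue's carbonyl oxygen on four chains.
    """
    sel = (traj.particles.mask(Species.PROTEIN_REF)
           & (traj.particles.residue_label == residue)
           & (traj.particles.atom_label == "O"))
    cols = np.flatnonzero(sel)
    chains = traj.particles.chain_id[cols]
    if len(np.unique(chains)) != 4 or len(cols) != 4:
        raise ConfigurationError(
            f"pore diameter needs the carbonyl O of {residue!r} on exactly 4 chains")
    pos = traj.positions[:, cols, :]
    # Pair chains by first-frame geometry: each chain with its farthest peer.
    first = pos[0]
    d0 = np.linalg.norm(first[:, None, :] - first[None, :, :], axis=-1)
    partner = int(np.argmax(d0[0]))
    rest = [i for i in range(1, 4) if i != partner]
    pairs = ((0, partner), tuple(rest))
    dists = [np.linalg.norm(pos[:, a, :] - pos[:, b, :], axis=-1) for a, b in pairs]
    return 0.5 * (dists[0] + dists[1])
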