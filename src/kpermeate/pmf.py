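"""Axial ion density, potential of mean force, and site occupancy.

The PMF is Boltzmann inversion of the equilibrium axial density of the
ions: ``W(z) = -ln[ n(z) / max n ]`` in units of kT, so the global
minimum is exactly zero at the density maximum.  Any additive constant
of a PMF is arbitrary; pinning the minimum gives a reproducible
convention.  Bins that collected no samples are reported as +inf and
flagged unsampled rather than interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DomainError
from .sites import FILTER_CODES, INSIDE_CODES, SITE_NAMES, SiteAssignment
from .trajectory import Species, Trajectory

__all__ = ["PMFProfile", "OccupancyTable", "axial_pmf", "occupancy_rates"]

DEFAULT_BIN_WIDTH = 0.2  # Angstrom; resolves the ~1 A site spacing


@dataclass(frozen=True)
class PMFProfile:
    """Histogram, normalised density and PMF (kT) on axial bins."""

    bin_centers: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    pmf_kt: np.ndarray
    bin_width: float

    @property
    def sampled(self) -> np.ndarray:
        """Mask of bins with at least one count (finite PMF)."""
        return self.counts > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_A": self.bin_centers, "count": self.counts,
                             "density": self.density, "pmf_kT": self.pmf_kt})


def axial_pmf(traj: Trajectory, z_range: Optional[tuple[float, float]] = None,
              bin_width: float = DEFAULT_BIN_WIDTH,
              species: Species = Species.K) -> PMFProfile:
    """PMF of the ions' axial density across all frames.

    ``z_range`` defaults to the data extent.  At least one ion position
    must fall inside the range.
    """
    if bin_width <= 0:
        raise DomainError("bin width must be positive")
    cols = np.flatnonzero(traj.particles.mask(species))
    z = (traj.axial()[:, cols]).reshape(-1)
    if z_range is None:
        if z.size == 0:
            raise DomainError("no ion positions available")
        z_range = (float(z.min()), float(z.max()) + 1e-9)
    lo, hi = map(float, z_range)
    if not hi > lo:
        raise DomainError("empty z range")
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(z, bins=edges)
    total = counts.sum()
    if total == 0:
        raise DomainError("no ion positions inside the requested z range")
    density = counts / total
    with np.errstate(divide="ignore"):
        pmf = -np.log(counts / counts.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PMFProfile(centers, counts, density, pmf, bin_width)


@dataclass(frozen=True)
class OccupancyTable:
    """Fraction of frames in which each site holds at least one ion."""

    sites: tuple[str, ...]
    fraction: np.ndarray

    def rate(self, site: str) -> float:
        return float(self.fraction[self.sites.index(site)])

    def as_dict(self) -> dict:
        return {s: float(f) for s, f in zip(self.sites, self.fraction)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site": self.sites, "occupancy": self.fraction})


def occupancy_rates(assign: SiteAssignment,
                    species: Species = Species.K) -> OccupancyTable:
    """Per-site occupancy rate: fraction of frames with >=1 ion present."""
    if assign.n_frames == 0:
        raise DomainError("occupancy of an empty trajectory is undefined")
    cols = np.flatnonzero(assign.species == species.value)
    labels = assign.labels[:, cols]
    fractions = np.array([
        np.mean(np.any(labels == code, axis=1)) if len(cols) else 0.0
        for code in INSIDE_CODES
    ])
    return OccupancyTable(SITE_NAMES, fractions)
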