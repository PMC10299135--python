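"""Permeation counting, flux/current/conductance, residence times.

A completed outward transit is counted with a two-plane hysteresis
rule: an ion contributes +1 when it reaches OUTSIDE_ABOVE having
previously been on the intracellular side (OUTSIDE_BELOW or S_cav)
without an intervening OUTSIDE_ABOVE; the mirror-image inward transit
contributes -1.  Mere recrossings of the S0 boundary that never reach
the cavity side are not transits.  This rule is exactly antisymmetric
under time reversal.

Currents use the elementary charge: ``I = n_crossings * e / T``; flux
is normalised to a 400 ns observation window; conductance ``G = I/V``
needs a user-supplied transmembrane voltage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .sites import (LABEL_NAMES, INSIDE_CODES, OUTSIDE_ABOVE, OUTSIDE_BELOW,
                    S_CAV, SITE_NAMES, SiteAssignment)
from .trajectory import Species

__all__ = [
    "ELEMENTARY_CHARGE", "FLUX_WINDOW_PS",
    "TransitEvent", "CrossingResult", "PermeationSummary", "ResidenceTable",
    "count_crossings", "summarize_permeation", "percent_change",
    "residence_times",
]

ELEMENTARY_CHARGE = 1.602176634e-19  # C
FLUX_WINDOW_PS = 400_000.0           # the 400 ns reporting window, ps


@dataclass(frozen=True)
class TransitEvent:
    """One completed transmembrane transit of a single ion."""

    particle_id: int
    frame: int
    time: float
    direction: int  # +1 outward, -1 inward


@dataclass(frozen=True)
class CrossingResult:
    outward: tuple[TransitEvent, ...]
    inward: tuple[TransitEvent, ...]

    @property
    def net(self) -> int:
        return len(self.outward) - len(self.inward)

    @property
    def n_permeating(self) -> int:
        """Number of completed outward permeations."""
        return len(self.outward)


def _transits_for_labels(labels: np.ndarray) -> tuple[list[int], list[int]]:
    """Frame indices of completed outward / inward transits for one ion.

    Works on the compressed sequence of LOW (below or S_cav) and HIGH
    (above) visits; filter frames carry no information for the
    hysteresis rule.
    """
    low = (labels == OUTSIDE_BELOW) | (labels == S_CAV)
    high = labels == OUTSIDE_ABOVE
    interesting = np.flatnonzero(low | high)
    outward: list[int] = []
    inward: list[int] = []
    state = 0  # 0 unknown, 1 low, 2 high
    for f in interesting:
        if low[f]:
            if state == 2:
                inward.append(int(f))
            state = 1
        else:
            if state == 1:
                outward.append(int(f))
            state = 2
    return outward, inward


def count_crossings(assign: SiteAssignment,
                    species: Species = Species.K) -> CrossingResult:
    """Detect completed transits for every tracked ion.

    Returns the outward and inward event lists; ``result.net`` is the
    signed crossing count (outward minus inward).
    """
    value = species.value
    cols = np.flatnonzero(assign.species == value)
    outward: list[TransitEvent] = []
    inward: list[TransitEvent] = []
    for c in cols:
        pid = int(assign.particle_ids[c])
        out_f, in_f = _transits_for_labels(assign.labels[:, c])
        outward += [TransitEvent(pid, f, float(assign.times[f]), +1) for f in out_f]
        inward += [TransitEvent(pid, f, float(assign.times[f]), -1) for f in in_f]
    outward.sort(key=lambda e: e.frame)
    inward.sort(key=lambda e: e.frame)
    return CrossingResult(tuple(outward), tuple(inward))


@dataclass(frozen=True)
class PermeationSummary:
    """Flux / current / conductance for one condition (Table-1 shape)."""

    crossing_count: int
    duration_ns: float
    flux_per_400ns: float
    current_pa: float
    conductance_ps: Optional[float] = None
    voltage_v: Optional[float] = None
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "condition": self.condition,
            "flux_per_400ns": self.flux_per_400ns,
            "current_pA": self.current_pa,
            "conductance_pS": self.conductance_ps,
        }])


def summarize_permeation(crossings: CrossingResult | int, duration_ps: float,
                         voltage: Optional[float] = None,
                         condition: str = "",
                         counting: str = "net") -> PermeationSummary:
    """Convert a crossing count over ``duration_ps`` into flux and current.

    ``counting`` selects net (default) or outward-only counts when a
    :class:`CrossingResult` is given.  Conductance is reported only when
    a transmembrane ``voltage`` (V) is supplied; the analysis itself has
    no way to know it.
    """
    if duration_ps <= 0:
        raise DomainError("duration must be positive")
    if isinstance(crossings, CrossingResult):
        count = crossings.net if counting == "net" else len(crossings.outward)
    else:
        count = int(crossings)
    flux = count * FLUX_WINDOW_PS / duration_ps
    current_pa = count * ELEMENTARY_CHARGE / (duration_ps * 1e-12) * 1e12
    conductance = None
    if voltage is not None:
        if voltage == 0:
            raise DomainError("voltage must be nonzero for conductance")
        conductance = current_pa / voltage
    return PermeationSummary(count, duration_ps / 1e3, flux, current_pa,
                             conductance, voltage, condition)


def percent_change(reference: float, value: float) -> float:
    """Relative change in percent, ``100 * (value - reference) / reference``."""
    if reference == 0:
        raise DomainError("reference must be nonzero for a percent change")
    return 100.0 * (value - reference) / reference


@dataclass(frozen=True)
class ResidenceTable:
    """Per-site dwell totals and mean residence times.

    The mean residence time of a site is the total time potassium ions
    spent there divided by the number of ions that completed an outward
    permeation; with zero permeating ions the totals are still reported
    and the means are undefined (NaN).
    """

    sites: tuple[str, ...]
    total_ps: np.ndarray
    mean_ps: np.ndarray
    n_permeating: int
    restricted_to_permeating: bool = False

    @property
    def defined(self) -> bool:
        return self.n_permeating > 0

    def total(self, site: str) -> float:
        return float(self.total_ps[self.sites.index(site)])

    def mean(self, site: str) -> float:
        return float(self.mean_ps[self.sites.index(site)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site": self.sites,
                             "total_dwell_ps": self.total_ps,
                             "mean_residence_ps": self.mean_ps})


def residence_times(assign: SiteAssignment, crossings: CrossingResult,
                    only_permeating: bool = False) -> ResidenceTable:
    """Total and mean dwell time of potassium ions in each site.

    Every frame a K+ ion spends in a site region contributes one
    sampling interval ``dt`` to that site's total.  By default all ions
    contribute to the totals ("the total time the potassium ions
    stayed", unqualified); ``only_permeating`` restricts the totals to
    ions that completed an outward permeation.
    """
    cols = assign.k_columns
    if only_permeating:
        permeated = {e.particle_id for e in crossings.outward}
        cols = np.array([c for c in cols
                         if int(assign.particle_ids[c]) in permeated], dtype=int)
    labels = assign.labels[:, cols] if len(cols) else np.zeros((assign.n_frames, 0), np.uint8)
    totals = np.array([np.count_nonzero(labels == code) * assign.dt
                       for code in INSIDE_CODES])
    n_perm = crossings.n_permeating
    means = totals / n_perm if n_perm > 0 else np.full(len(totals), np.nan)
    return ResidenceTable(SITE_NAMES, totals, means, n_perm, only_permeating)
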