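"""Selectivity-filter loading states and knock-on mode classification.

The loading state is the occupancy pattern of the five filter sites
read from S4 (entry) to S0 (exit): ``K`` for a potassium ion, ``W`` for
a water oxygen, ``O`` for a vacancy.  The condensed form drops the
vacancies.  When an ion completes an outward permeation, the loading
state of the frame *before* the exit frame is recorded and classified:

* condensed ``KKK``            -> direct knock-on (ion-ion contact),
* condensed ``KWKWK``          -> soft knock-on (alternating ion/water),
* condensed ``KWKK`` / ``KKWK`` -> mixed knock-on (a single water),
* anything else                -> OTHER (reported separately, never
  silently merged into a named mode).

A generalised rule is available as an option: count the waters strictly
between the first and last ion of the condensed string (0 -> direct,
1 -> mixed, >=2 -> soft; at least two ions required).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .permeation import CrossingResult, count_crossings
from .sites import FILTER_CODES, SiteAssignment
from .trajectory import Species

__all__ = [
    "Mode", "LoadingState", "PermeationEvent", "ModeProportions",
    "loading_state", "classify_mode", "detect_events", "mode_proportions",
]


class Mode(str, enum.Enum):
    SOFT = "SOFT"
    DIRECT = "DIRECT"
    MIXED = "MIXED"
    OTHER = "OTHER"


@dataclass(frozen=True)
class LoadingState:
    """Occupancy string of S4..S0 plus its vacancy-free condensed form."""

    raw: str

    def __post_init__(self) -> None:
        if len(self.raw) != 5 or set(self.raw) - set("KWO"):
            raise ValueError(f"not a loading state over K/W/O of length 5: {self.raw!r}")

    @property
    def condensed(self) -> str:
        return self.raw.replace("O", "")

    def __str__(self) -> str:
        return self.raw


def loading_state(assign: SiteAssignment, frame_index: int) -> LoadingState:
    """Loading state of the filter at one frame.

    Per site S4..S0: ``K`` if a potassium occupies it, else ``W`` if a
    water oxygen does, else ``O``.  If both an ion and a water fall in
    one site the ion wins (ion presence defines the electrostatic state
    of the site).
    """
    row = assign.labels[frame_index]
    is_k = assign.species == Species.K.value
    is_w = assign.species == Species.WATER_O.value
    chars = []
    for code in FILTER_CODES:  # S4..S0
        here = row == code
        if np.any(here & is_k):
            chars.append("K")
        elif np.any(here & is_w):
            chars.append("W")
        else:
            chars.append("O")
    return LoadingState("".join(chars))


_LITERAL = {"KKK": Mode.DIRECT, "KWKWK": Mode.SOFT,
            "KWKK": Mode.MIXED, "KKWK": Mode.MIXED}


def classify_mode(state: LoadingState | str, rule: str = "literal") -> Mode:
    """Classify a loading state into a knock-on mode.

    ``rule="literal"`` (default) recognises exactly the enumerated
    condensed strings; ``rule="general"`` counts interior waters between
    the first and last ion.
    """
    condensed = state.condensed if isinstance(state, LoadingState) else \
        str(state).replace("O", "")
    if rule == "literal":
        return _LITERAL.get(condensed, Mode.OTHER)
    if rule == "general":
        if condensed.count("K") < 2:
            return Mode.OTHER
        interior = condensed[condensed.index("K") + 1:condensed.rindex("K")]
        waters = interior.count("W")
        return Mode.DIRECT if waters == 0 else Mode.MIXED if waters == 1 else Mode.SOFT
    raise ValueError(f"unknown classification rule {rule!r}")


@dataclass(frozen=True)
class PermeationEvent:
    """One outward ion exit with the pre-exit loading state and mode."""

    particle_id: int
    exit_frame: int
    exit_time: float
    state_before: Optional[LoadingState]
    mode: Mode


def detect_events(assign: SiteAssignment,
                  crossings: Optional[CrossingResult] = None,
                  rule: str = "literal") -> list[PermeationEvent]:
    """Per completed outward permeation, record and classify the event.

    Events are the completed outward transits of the hysteresis counter,
    so the number of events always equals the outward crossing count of
    the same trajectory.  The loading state is taken at the frame
    preceding the exit frame; an exit already present at frame 0 has no
    previous frame and is classified OTHER with a warning.
    """
    if crossings is None:
        crossings = count_crossings(assign)
    events: list[PermeationEvent] = []
    for transit in crossings.outward:
        if transit.frame == 0:
            warnings.warn("outward exit at frame 0 has no previous frame; "
                          "classified OTHER")
            events.append(PermeationEvent(transit.particle_id, 0,
                                          transit.time, None, Mode.OTHER))
            continue
        state = loading_state(assign, transit.frame - 1)
        events.append(PermeationEvent(transit.particle_id, transit.frame,
                                      transit.time, state,
                                      classify_mode(state, rule=rule)))
    return events


@dataclass(frozen=True)
class ModeProportions:
    """Counts and fractions of knock-on modes over a set of events."""

    counts: dict
    n_events: int

    @property
    def defined(self) -> bool:
        return self.n_events > 0

    @property
    def fractions(self) -> Optional[dict]:
        if not self.defined:
            return None
        return {m: c / self.n_events for m, c in self.counts.items()}

    def to_frame(self, condition: str = "") -> pd.DataFrame:
        fr = self.fractions or {m: np.nan for m in self.counts}
        return pd.DataFrame({
            "condition": [condition] * len(self.counts),
            "mode": [m.value for m in self.counts],
            "count": list(self.counts.values()),
            "fraction": [fr[m] for m in self.counts],
        })


def mode_proportions(events: Sequence[PermeationEvent]) -> ModeProportions:
    """Tally mode counts and fractions; empty input flags undefined fractions."""
    counts = {m: 0 for m in Mode}
    for e in events:
        counts[e.mode] += 1
    return ModeProportions(counts, len(events))


def events_to_frame(events: Sequence[PermeationEvent]) -> pd.DataFrame:
    """Events as a CSV-ready table (ion, time, raw/condensed state, mode)."""
    return pd.DataFrame({
        "particle_id": [e.particle_id for e in events],
        "exit_frame": [e.exit_frame for e in events],
        "exit_time_ps": [e.exit_time for e in events],
        "state_raw_S4_to_S0": [e.state_before.raw if e.state_before else ""
                               for e in events],
        "state_condensed": [e.state_before.condensed if e.state_before else ""
                            for e in events],
        "mode": [e.mode.value for e in events],
    })
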