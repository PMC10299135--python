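"""Synthetic trajectories and signals with known ground truth.

MD trajectories of ion permeation are expensive and no public dataset
accompanies the analyses this package implements, so every statistical
structure the analysis stages assume is emulated by a generator whose
ground truth is known by construction:

* :func:`gen_sf_markov` - a continuous-time Markov chain over filter
  loading states, realised as particle positions with persistent ion
  identities; exits past S0 and per-site dwell intervals are logged.
* :func:`gen_boltzmann_1d` - positions drawn from ``exp(-U(z))`` for a
  known 1-D potential (oracle for Boltzmann-inversion PMFs).
* :func:`gen_oscillator_velocity` - a cosine velocity trace at a known
  frequency (oracle for VACF power spectra).
* :func:`gen_hbond_telegraph` - a two-state bonded/unbonded process
  with exponential dwells rendered as donor/H/acceptor geometry.
* :func:`gen_crossings` - ions transiting the pore at scheduled times
  (oracle for flux counting).

All generators are pure functions of their arguments and an explicit
integer seed (numpy ``default_rng``); identical inputs give bit-identical
outputs.  Quantities the quasi-static field treatment needs -- the
waveform ``E(t) = E0 cos[w (t - t0)]`` and the magnetic/electric force
ratio ``v/c`` -- live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .sites import REFERENCE_ATOMS, S_CAV_DEPTH
from .trajectory import Particles, Species, Trajectory

__all__ = [
    "SPEED_OF_LIGHT", "DEFAULT_SITE_CENTERS",
    "FieldWaveform", "field_at", "force_ratio",
    "SFMarkovSpec", "ExitEvent", "DwellInterval", "GroundTruth",
    "gen_sf_markov", "gen_boltzmann_1d", "gen_oscillator_velocity",
    "TelegraphGroundTruth", "gen_hbond_telegraph", "gen_crossings",
    "write_ground_truth",
]

SPEED_OF_LIGHT = 2.99792458e8  # m/s

#: Default axial site centers (S_cav, S4, S3, S2, S1, S0), Angstrom.
#: Boundary rings fall midway between filter sites, 3 A apart, which is
#: the canonical carbonyl-ring spacing scale of K+ channel filters.
DEFAULT_SITE_CENTERS = (-1.5, 1.5, 4.5, 7.5, 10.5, 13.5)

_PARK_MARGIN = 6.0     # parked particles sit this far outside the filter, A
_REF_ID_BASE = 100_000
_WATER_ID_BASE = 10_000
_WATER_H_ID_BASE = 50_000

# Independent copy of the literal mode vocabulary used for ground truth,
# applied to the vacancy-free form of the pre-exit state.
_TRUE_MODE = {"KKK": "DIRECT", "KWKWK": "SOFT", "KWKK": "MIXED", "KKWK": "MIXED"}


# ---------------------------------------------------------------------------
# Quasi-static field model


@dataclass(frozen=True)
class FieldWaveform:
    """External field ``E(t) = E0 cos[2 pi f (t - t0)]``.

    ``E0`` in V/nm, ``freq`` in THz, ``t0`` (phase reference) in ps.
    """

    E0: float
    freq: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.E0 < 0 or self.freq < 0:
            raise ValueError("amplitude and frequency must be non-negative")


def field_at(waveform: FieldWaveform, t: float | np.ndarray) -> float | np.ndarray:
    """Field value(s) in V/nm at time(s) ``t`` (ps)."""
    value = waveform.E0 * np.cos(2.0 * np.pi * waveform.freq
                                 * (np.asarray(t, dtype=float) - waveform.t0))
    return float(value) if np.isscalar(t) else value


def force_ratio(speed: float) -> float:
    """Magnetic-to-electric force ratio ``v / c`` for a charge in a plane wave.

    For any particle far slower than light the magnetic force is
    negligible, which justifies treating the THz wave as a purely
    electric, spatially uniform field.
    """
    if not 0 <= speed < SPEED_OF_LIGHT:
        raise DomainError("speed must satisfy 0 <= v < c")
    return speed / SPEED_OF_LIGHT


# ---------------------------------------------------------------------------
# Shared geometry helpers


def site_edges_from_centers(site_centers: Sequence[float]) -> np.ndarray:
    """The 7 region boundaries implied by the 6 site centers.

    Filter boundaries fall midway between adjacent filter sites; the
    outer boundaries extrapolate half a spacing beyond S4 and S0, and
    the cavity site extends :data:`S_CAV_DEPTH` below the bottom ring.
    """
    c = np.asarray(site_centers, dtype=float)
    if c.shape != (6,) or np.any(np.diff(c) <= 0):
        raise ConfigurationError("site_centers must be 6 strictly increasing values")
    sf = c[1:]
    mids = 0.5 * (sf[:-1] + sf[1:])
    b0 = sf[0] - (mids[0] - sf[0])
    b5 = sf[-1] + (sf[-1] - mids[-1])
    edges = np.concatenate(([b0 - S_CAV_DEPTH, b0], mids, [b5]))
    if not (edges[0] <= c[0] < edges[1]):
        raise ConfigurationError("S_cav center must lie inside the cavity region")
    return edges


def _scaffold(site_centers: Sequence[float]) -> tuple[list[tuple], np.ndarray]:
    """Reference-oxygen particle rows and their static positions.

    Four chains (A-D) on a 2 A radius, one ring per region boundary, so
    that site maps built from synthetic frames reproduce the intended
    geometry through the ordinary :func:`~kpermeate.sites.build_site_map`
    code path.
    """
    edges = site_edges_from_centers(site_centers)
    ring_z = edges[1:]   # hydroxyl ring upward; the cavity floor has no atoms
    xy = [(2.0, 0.0), (0.0, 2.0), (-2.0, 0.0), (0.0, -2.0)]
    chains = ["A", "B", "C", "D"]
    rows, pos = [], []
    pid = _REF_ID_BASE
    for j, (residue, atom) in enumerate(REFERENCE_ATOMS):
        for (x, y), chain in zip(xy, chains):
            rows.append((pid, Species.PROTEIN_REF.value, residue, atom, chain))
            pos.append((x, y, ring_z[j]))
            pid += 1
    return rows, np.asarray(pos)


# ---------------------------------------------------------------------------
# Loading-state Markov generator


@dataclass(frozen=True)
class SFMarkovSpec:
    """Specification of a loading-state Markov chain.

    ``states`` are raw occupancy strings over ``{K, W, O}`` for sites
    S4..S0 in entry-to-exit order.  ``rates`` maps ``(from, to)`` state
    strings to transition rates in 1/ps.  ``exit_transitions`` declares
    which transitions carry the topmost ion past the S0 upper bound;
    their origin state must hold a K in S0.  All other transitions are
    realised as in-filter rearrangements, entries from the cavity side
    and returns to it.
    """

    states: tuple[str, ...]
    rates: Mapping[tuple[str, str], float]
    exit_transitions: frozenset = frozenset()
    site_centers: tuple[float, ...] = DEFAULT_SITE_CENTERS
    jitter_sigma: float = 0.15
    dt: float = 0.5
    duration: float = 1000.0
    seed: int = 0
    initial_state: int = 0

    def __post_init__(self) -> None:
        for s in self.states:
            if len(s) != 5 or set(s) - set("KWO"):
                raise ConfigurationError(f"bad loading state {s!r}")
        if len(set(self.states)) != len(self.states):
            raise ConfigurationError("duplicate loading states")
        index = {s: i for i, s in enumerate(self.states)}
        for (a, b), rate in self.rates.items():
            if a not in index or b not in index:
                raise ConfigurationError(f"rate for unknown state pair {(a, b)!r}")
            if a == b:
                raise ConfigurationError("self-transitions are not allowed")
            if rate < 0:
                raise ConfigurationError("rates must be non-negative")
        for a, b in self.exit_transitions:
            if (a, b) not in self.rates:
                raise ConfigurationError(f"exit transition {(a, b)!r} has no rate")
            if a[4] != "K":
                raise ConfigurationError(
                    f"exit transition from {a!r} needs a K in S0")
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigurationError("dt and duration must be positive")

    @property
    def rate_matrix(self) -> np.ndarray:
        """Generator matrix Q (off-diagonal rates, rows sum to zero)."""
        n = len(self.states)
        index = {s: i for i, s in enumerate(self.states)}
        q = np.zeros((n, n))
        for (a, b), rate in self.rates.items():
            q[index[a], index[b]] = rate
        np.fill_diagonal(q, -q.sum(axis=1))
        return q


@dataclass(frozen=True)
class ExitEvent:
    """Ground-truth outward exit of one ion."""

    time: float
    frame: int
    particle_id: int
    state_before: str       # raw S4..S0 string
    mode: str               # literal-vocabulary mode, "OTHER" if outside it


@dataclass(frozen=True)
class DwellInterval:
    """Ground-truth stay of one ion at one site, ``[t_start, t_end)`` ps."""

    site: str
    particle_id: int
    t_start: float
    t_end: float


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    events: list
    dwell_intervals: list
    crossing_count: int
    params: dict
    warnings: list = field(default_factory=list)
    stationary_states: Optional[dict] = None
    stationary_site_occupancy: Optional[dict] = None
    frame_states: Optional[np.ndarray] = None
    untracked_exits: int = 0


def _stationary(q: np.ndarray) -> Optional[np.ndarray]:
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    if np.any(pi < -1e-9):
        return None
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _k_sites(state: str) -> list[int]:
    return [i for i, ch in enumerate(state) if ch == "K"]


def _w_sites(state: str) -> list[int]:
    return [i for i, ch in enumerate(state) if ch == "W"]


def _match_ions(a: str, b: str, is_exit: bool):
    """Ion bookkeeping for a transition ``a -> b``.

    Declared exits remove the topmost ion past S0; when more ions must
    disappear than the target state holds, the surplus returns to the
    cavity from the bottom.  Surviving ions map order-preservingly onto
    the target sites above any entrants, which come in from the cavity
    side.  Returns ``(exit_site, bottom_removed, moves, entries)``.
    """
    ka, kb = _k_sites(a), _k_sites(b)
    e_top = 1 if is_exit else 0
    e_bot = max(0, len(ka) - e_top - len(kb))
    n_in = len(kb) - (len(ka) - e_top - e_bot)
    survivors = ka[e_bot:len(ka) - e_top] if e_top else ka[e_bot:]
    moves = list(zip(survivors, kb[n_in:]))
    exit_site = ka[-1] if e_top else None
    return exit_site, ka[:e_bot], moves, kb[:n_in]


def _match_waters(a: str, b: str, ion_exited: bool):
    """Water bookkeeping: surplus waters co-exit above when an ion exits,
    otherwise they return to the cavity below."""
    wa, wb = _w_sites(a), _w_sites(b)
    n_rem = max(0, len(wa) - len(wb))
    if ion_exited:
        removed, survivors = wa[len(wa) - n_rem:], wa[:len(wa) - n_rem]
        removed_above = True
    else:
        removed, survivors = wa[:n_rem], wa[n_rem:]
        removed_above = False
    n_in = len(wb) - len(survivors)
    moves = list(zip(survivors, wb[n_in:]))
    return removed, removed_above, moves, wb[:n_in]


_BELOW, _ABOVE = -1, 5   # timeline location codes besides site indices 0..4


class _Slot:
    """Lifetime of one synthetic particle: piecewise-constant location."""

    __slots__ = ("pid", "timeline", "entered_from_below")

    def __init__(self, pid: int, frame: int, loc: int, from_below: bool):
        self.pid = pid
        self.timeline: list[tuple[int, int]] = []
        self.entered_from_below = from_below
        if frame > 0:
            self.timeline.append((0, _BELOW))
        self.timeline.append((frame, loc))

    def move(self, frame: int, loc: int) -> None:
        if self.timeline[-1][0] == frame:
            self.timeline[-1] = (frame, loc)
        else:
            self.timeline.append((frame, loc))


def gen_sf_markov(spec: SFMarkovSpec) -> tuple[Trajectory, GroundTruth]:
    """Sample the loading-state chain and realise it as a trajectory.

    The chain is simulated exactly (Gillespie); transitions are then
    serialised onto the frame grid so that each frame-to-frame step
    realises at most one transition -- the frame before an exit
    therefore shows exactly the pre-transition loading state.  Each
    occupant sits at its site center plus Gaussian axial jitter; ions
    yet to enter (or waters) are parked below the cavity, exited
    particles above S0, so the hysteresis transit counter sees complete
    permeations.  Ions already in the filter at frame 0 never complete
    a transit; their eventual exits are tallied separately and excluded
    from the ground-truth events.
    """
    rng = np.random.default_rng(spec.seed)
    q = spec.rate_matrix
    index = {s: i for i, s in enumerate(spec.states)}
    n_frames = int(math.floor(spec.duration / spec.dt)) + 1
    warnings_list: list[str] = []

    # --- exact chain simulation
    transitions: list[tuple[float, int, int]] = []
    state = spec.initial_state
    t = 0.0
    while True:
        out_rate = -q[state, state]
        if out_rate <= 0:
            if not transitions and not spec.rates:
                warnings_list.append("all rates are zero; static trajectory")
            else:
                warnings_list.append(
                    f"absorbing state {spec.states[state]!r}; chain stopped")
            break
        t += rng.exponential(1.0 / out_rate)
        if t >= spec.duration:
            break
        probs = q[state].copy()
        probs[state] = 0.0
        nxt = int(rng.choice(len(probs), p=probs / probs.sum()))
        transitions.append((t, state, nxt))
        state = nxt

    # --- serialise onto the grid: one transition per frame boundary
    grid_transitions: list[tuple[int, int, int]] = []
    last_frame = 0
    for t, a, b in transitions:
        f = max(last_frame + 1, int(math.ceil(t / spec.dt - 1e-12)))
        if f >= n_frames:
            break
        grid_transitions.append((f, a, b))
        last_frame = f

    frame_states = np.empty(n_frames, dtype=np.int64)
    cursor, current = 0, spec.initial_state
    for f, a, b in grid_transitions:
        frame_states[cursor:f] = current
        cursor, current = f, b
    frame_states[cursor:] = current

    # --- particle bookkeeping
    ion_slots: list[_Slot] = []
    water_slots: list[_Slot] = []
    site_ion: dict[int, _Slot] = {}
    site_water: dict[int, _Slot] = {}
    events: list[ExitEvent] = []
    untracked = 0

    def new_ion(frame: int, site: int, from_below: bool) -> _Slot:
        slot = _Slot(len(ion_slots), frame, site, from_below)
        ion_slots.append(slot)
        return slot

    def new_water(frame: int, site: int, from_below: bool) -> _Slot:
        slot = _Slot(_WATER_ID_BASE + len(water_slots), frame, site, from_below)
        water_slots.append(slot)
        return slot

    init = spec.states[spec.initial_state]
    for s in _k_sites(init):
        site_ion[s] = new_ion(0, s, from_below=False)
    for s in _w_sites(init):
        site_water[s] = new_water(0, s, from_below=False)

    exit_pairs = {(a, b) for a, b in spec.exit_transitions}
    for f, ai, bi in grid_transitions:
        a, b = spec.states[ai], spec.states[bi]
        is_exit = (a, b) in exit_pairs
        exit_site, removed_bot, moves, entries = _match_ions(a, b, is_exit)
        time = f * spec.dt

        if exit_site is not None:
            slot = site_ion.pop(exit_site)
            slot.move(f, _ABOVE)
            if slot.entered_from_below:
                events.append(ExitEvent(time, f, slot.pid, a,
                                        _TRUE_MODE.get(a.replace("O", ""), "OTHER")))
            else:
                untracked += 1
        for s in removed_bot:
            site_ion.pop(s).move(f, _BELOW)
        moved = [(site_ion.pop(src), dst) for src, dst in moves]
        for slot, dst in moved:
            slot.move(f, dst)
            site_ion[dst] = slot
        for s in entries:
            site_ion[s] = new_ion(f, s, from_below=True)

        removed_w, above, wmoves, wentries = _match_waters(a, b, is_exit)
        for s in removed_w:
            site_water.pop(s).move(f, _ABOVE if above else _BELOW)
        wmoved = [(site_water.pop(src), dst) for src, dst in wmoves]
        for slot, dst in wmoved:
            slot.move(f, dst)
            site_water[dst] = slot
        for s in wentries:
            site_water[s] = new_water(f, s, from_below=True)

    # --- render positions
    edges = site_edges_from_centers(spec.site_centers)
    sf_centers = np.asarray(spec.site_centers[1:])
    z_below = edges[0] - _PARK_MARGIN
    z_above = edges[-1] + _PARK_MARGIN
    loc_z = {_BELOW: z_below, _ABOVE: z_above,
             **{s: sf_centers[s] for s in range(5)}}

    slots = ion_slots + water_slots
    n_dyn = len(slots)
    z = np.empty((n_frames, n_dyn))
    dwells: list[DwellInterval] = []
    site_names = ("S4", "S3", "S2", "S1", "S0")
    for col, slot in enumerate(slots):
        timeline = slot.timeline + [(n_frames, _BELOW)]
        for (f0, loc), (f1, _) in zip(timeline[:-1], timeline[1:]):
            z[f0:f1, col] = loc_z[loc]
            if 0 <= loc <= 4 and col < len(ion_slots):
                dwells.append(DwellInterval(site_names[loc], slot.pid,
                                            f0 * spec.dt, f1 * spec.dt))
    if spec.jitter_sigma > 0:
        z += rng.normal(0.0, spec.jitter_sigma, size=z.shape)

    ref_rows, ref_pos = _scaffold(spec.site_centers)
    rows = ([(s.pid, Species.K.value, "", "K", "") for s in ion_slots]
            + [(s.pid, Species.WATER_O.value, "", "OW", "") for s in water_slots]
            + ref_rows)
    particles = Particles.build(rows)

    positions = np.zeros((n_frames, n_dyn + len(ref_rows), 3))
    positions[:, :n_dyn, 2] = z
    positions[:, n_dyn:, :] = ref_pos[None, :, :]

    times = spec.dt * np.arange(n_frames)
    traj = Trajectory(particles, times, positions, dt=spec.dt,
                      metadata={"generator": "sf_markov", "seed": spec.seed})

    pi = _stationary(q) if spec.rates else None
    site_occ = None
    if pi is not None:
        site_occ = {name: float(sum(pi[i] for i, s in enumerate(spec.states)
                                    if s[j] == "K"))
                    for j, name in enumerate(site_names)}
    gt = GroundTruth(
        events=events, dwell_intervals=dwells, crossing_count=len(events),
        params={"states": spec.states, "dt": spec.dt,
                "duration": spec.duration, "seed": spec.seed,
                "jitter_sigma": spec.jitter_sigma},
        warnings=warnings_list,
        stationary_states=(None if pi is None else
                           {s: float(pi[i]) for i, s in enumerate(spec.states)}),
        stationary_site_occupancy=site_occ,
        frame_states=frame_states,
        untracked_exits=untracked,
    )
    return traj, gt


# ---------------------------------------------------------------------------
# Boltzmann sampler


def gen_boltzmann_1d(potential: Callable[[np.ndarray], np.ndarray],
                     z_range: tuple[float, float], n: int, seed: int,
                     dt: float = 1.0, grid_points: int = 4001) -> Trajectory:
    """Single-ion frames with axial positions distributed as ``exp(-U(z))``.

    Inverse-CDF sampling on a dense grid; ``potential`` takes z in
    Angstrom and returns energy in kT.  Deterministic under ``seed``.
    """
    lo, hi = map(float, z_range)
    if not hi > lo:
        raise DomainError("z_range must be a non-empty interval")
    grid = np.linspace(lo, hi, grid_points)
    u = np.asarray(potential(grid), dtype=float)
    if not np.all(np.isfinite(u)):
        raise DomainError("potential must be finite on the sampling range")
    p = np.exp(-(u - u.min()))
    cdf = np.concatenate(([0.0], np.cumsum(0.5 * (p[1:] + p[:-1])
                                           * np.diff(grid))))
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    zs = np.interp(rng.random(n), cdf, grid)

    particles = Particles.build([(0, Species.K.value, "", "K", "")])
    positions = np.zeros((n, 1, 3))
    positions[:, 0, 2] = zs
    return Trajectory(particles, dt * np.arange(n), positions, dt=dt,
                      metadata={"generator": "boltzmann_1d", "seed": seed})


# ---------------------------------------------------------------------------
# Oscillator velocities


def gen_oscillator_velocity(f0: float, dt: float, duration: float,
                            noise_sigma: float = 0.0,
                            seed: Optional[int] = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Velocity trace ``v(t) = cos(2 pi f0 t)`` plus Gaussian noise.

    Returns ``(times_ps, v)``.  ``f0`` must lie below the Nyquist
    frequency ``1 / (2 dt)``.
    """
    if dt <= 0 or duration <= 0:
        raise DomainError("dt and duration must be positive")
    if f0 < 0:
        raise DomainError("frequency must be non-negative")
    if f0 > 0 and dt * f0 >= 0.5:
        raise DomainError(
            f"f0 = {f0} THz is at or above the Nyquist frequency "
            f"{0.5 / dt} THz for dt = {dt} ps")
    n = int(round(duration / dt))
    t = dt * np.arange(n)
    v = np.cos(2.0 * np.pi * f0 * t)
    if noise_sigma > 0:
        v = v + np.random.default_rng(seed).normal(0.0, noise_sigma, n)
    return t, v


# ---------------------------------------------------------------------------
# Hydrogen-bond telegraph process


@dataclass(frozen=True)
class TelegraphGroundTruth:
    """True bonded/unbonded intervals of the telegraph process."""

    on_intervals: tuple    # ((t0, t1), ...), clipped to the trajectory span
    off_intervals: tuple
    tau_on: float
    tau_off: float

    @property
    def on_dwells(self) -> np.ndarray:
        return np.array([t1 - t0 for t0, t1 in self.on_intervals])


def gen_hbond_telegraph(tau_on: float, tau_off: float, dt: float,
                        duration: float, seed: int,
                        start_on: bool = True
                        ) -> tuple[Trajectory, TelegraphGroundTruth]:
    """Two-state donor/H/acceptor geometry with exponential dwells.

    While bonded the donor-acceptor distance is 2.9 A and the
    hydrogen-donor-acceptor angle 15 deg (inside the 3.5 A / 30 deg
    criteria); while unbonded the distance is 5.0 A.  ``tau_off`` may be
    ``inf`` to produce a single bonded interval.
    """
    if tau_on <= 0 or tau_off <= 0:
        raise DomainError("dwell time constants must be positive")
    if dt <= 0 or duration <= 0:
        raise DomainError("dt and duration must be positive")
    rng = np.random.default_rng(seed)

    boundaries: list[float] = []
    t, on = 0.0, start_on
    while t < duration:
        tau = tau_on if on else tau_off
        dwell = rng.exponential(tau) if np.isfinite(tau) else np.inf
        t = min(t + dwell, duration) if np.isfinite(dwell) else duration
        boundaries.append(t)
        on = not on
    bounds = np.asarray(boundaries)

    n = int(math.floor(duration / dt)) + 1
    times = dt * np.arange(n)
    seg = np.searchsorted(bounds, times, side="right")
    on_frames = (seg % 2 == 0) if start_on else (seg % 2 == 1)

    starts = np.concatenate(([0.0], bounds[:-1]))
    ends = bounds
    is_on = (np.arange(len(bounds)) % 2 == 0) if start_on else \
        (np.arange(len(bounds)) % 2 == 1)
    on_iv = tuple((float(a), float(b)) for a, b, o in zip(starts, ends, is_on) if o)
    off_iv = tuple((float(a), float(b)) for a, b, o in zip(starts, ends, is_on) if not o)

    d_on, d_off = 2.9, 5.0
    theta = np.deg2rad(15.0)
    d = np.where(on_frames, d_on, d_off)
    positions = np.zeros((n, 3, 3))
    positions[:, 1, 0] = d                         # donor O
    positions[:, 2, 0] = d - 0.96 * np.cos(theta)  # H, 15 deg off the D->A line
    positions[:, 2, 1] = 0.96 * np.sin(theta)

    particles = Particles.build([
        (0, Species.PROTEIN_REF.value, "374THR", "OG1", "A"),
        (1, Species.WATER_O.value, "", "OW", ""),
        (2, Species.WATER_H.value, "", "HW", ""),
    ])
    traj = Trajectory(particles, times, positions, dt=dt,
                      metadata={"generator": "hbond_telegraph", "seed": seed})
    return traj, TelegraphGroundTruth(on_iv, off_iv, tau_on, tau_off)


# ---------------------------------------------------------------------------
# Scheduled-crossing generator


def gen_crossings(schedule: Sequence[float], duration: float, dt: float,
                  site_centers: Sequence[float] = DEFAULT_SITE_CENTERS,
                  transit_ps: float = 10.0) -> Trajectory:
    """One ion per scheduled crossing, ramping monotonically through the pore.

    Each ion moves linearly from well below the cavity to well above S0
    over a ``transit_ps`` window centered on its scheduled time and is
    stationary otherwise; the trajectory therefore contains exactly
    ``len(schedule)`` complete outward transits.
    """
    if dt <= 0 or duration <= 0:
        raise DomainError("dt and duration must be positive")
    half = transit_ps / 2.0
    for tc in schedule:
        if not (half <= tc <= duration - half):
            raise DomainError(
                f"scheduled crossing at {tc} ps does not fit inside the "
                f"{duration} ps trajectory (transit window {transit_ps} ps)")
    edges = site_edges_from_centers(site_centers)
    z_lo, z_hi = edges[0] - _PARK_MARGIN, edges[-1] + _PARK_MARGIN

    n = int(math.floor(duration / dt)) + 1
    times = dt * np.arange(n)
    n_ions = len(schedule)
    z = np.empty((n, n_ions))
    for k, tc in enumerate(schedule):
        frac = np.clip((times - (tc - half)) / transit_ps, 0.0, 1.0)
        z[:, k] = z_lo + (z_hi - z_lo) * frac

    ref_rows, ref_pos = _scaffold(site_centers)
    rows = [(k, Species.K.value, "", "K", "") for k in range(n_ions)] + ref_rows
    positions = np.zeros((n, n_ions + len(ref_rows), 3))
    positions[:, :n_ions, 2] = z
    positions[:, n_ions:, :] = ref_pos[None, :, :]
    return Trajectory(Particles.build(rows), times, positions, dt=dt,
                      metadata={"generator": "crossings",
                                "scheduled": list(map(float, schedule))})


# ---------------------------------------------------------------------------
# Ground-truth serialisation


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    """Serialise ground truth as key/value lines plus an event table."""
    path = Path(path)
    lines = [f"crossing_count: {gt.crossing_count}",
             f"untracked_exits: {gt.untracked_exits}"]
    for key, value in gt.params.items():
        lines.append(f"param.{key}: {value}")
    for w in gt.warnings:
        lines.append(f"warning: {w}")
    if gt.stationary_states:
        for s, p in gt.stationary_states.items():
            lines.append(f"stationary.{s}: {p:.8f}")
    lines.append("events: time_ps frame particle_id state_before mode")
    for e in gt.events:
        lines.append(f"  {e.time:.6f} {e.frame} {e.particle_id} "
                     f"{e.state_before} {e.mode}")
    path.write_text("\n".join(lines) + "\n")
    return path
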