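"""Geometric hydrogen-bond detection and lifetime estimation.

A donor-hydrogen-acceptor triplet is bonded in a frame when the
donor-acceptor distance is below 3.5 Angstrom and the bond angle is
below 30 degrees.  Two angle conventions exist in the literature and
the wording of geometric criteria is often ambiguous; both are
implemented:

* ``"hda"`` (default): the angle at the donor between the donor->H and
  donor->acceptor vectors,
* ``"dha_deviation"``: the deviation of the donor-H...acceptor angle
  from linearity (180 degrees minus the angle at the hydrogen).

Lifetimes come from the on/off bit pattern: the *continuous* lifetime
is the mean length of uninterrupted bonded intervals (any off frame
breaks the bond; intervals touching the trajectory ends are censored
and excluded by default), and the *survival* lifetime is the integral
of the normalised continuous-survival function, sum(L^2) / (2 sum(L)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .trajectory import Trajectory

__all__ = ["HBondCriteria", "BondInterval", "HBondTrace",
           "detect_hbonds", "lifetime", "LifetimeEstimate"]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria."""

    max_da_distance: float = 3.5    # Angstrom
    max_angle_deg: float = 30.0
    angle_convention: str = "hda"   # "hda" or "dha_deviation"

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_angle_deg < 180:
            raise ValueError("angle cutoff must lie in (0, 180) degrees")
        if self.angle_convention not in ("hda", "dha_deviation"):
            raise ValueError(f"unknown angle convention {self.angle_convention!r}")


@dataclass(frozen=True)
class BondInterval:
    """One uninterrupted bonded interval of a donor-acceptor pair."""

    pair: tuple[int, int]
    start_frame: int
    n_frames: int
    dt: float
    censored: bool      # touches either trajectory end

    @property
    def length_ps(self) -> float:
        return self.n_frames * self.dt


@dataclass
class HBondTrace:
    """Per-frame bond existence and the derived dwell intervals."""

    pairs: list[tuple[int, int]]        # (donor_id, acceptor_id)
    exists: np.ndarray                  # (n_frames, n_pairs) bool
    times: np.ndarray
    dt: float
    criteria: HBondCriteria

    @property
    def n_frames(self) -> int:
        return self.exists.shape[0]

    def intervals(self) -> list[BondInterval]:
        out: list[BondInterval] = []
        F = self.n_frames
        for j, pair in enumerate(self.pairs):
            bits = self.exists[:, j]
            padded = np.concatenate(([False], bits, [False]))
            flips = np.flatnonzero(np.diff(padded.astype(np.int8)))
            starts, ends = flips[0::2], flips[1::2]
            for s, e in zip(starts, ends):
                out.append(BondInterval(pair, int(s), int(e - s), self.dt,
                                        censored=(s == 0 or e == F)))
        return out

    def to_frame(self) -> pd.DataFrame:
        F, P = self.exists.shape
        return pd.DataFrame({
            "frame": np.repeat(np.arange(F), P),
            "time_ps": np.repeat(self.times, P),
            "donor_id": np.tile([p[0] for p in self.pairs], F),
            "acceptor_id": np.tile([p[1] for p in self.pairs], F),
            "bonded": self.exists.reshape(-1).astype(int),
        })


def detect_hbonds(traj: Trajectory,
                  donors: Sequence[tuple[int, int]],
                  acceptors: Sequence[int],
                  criteria: Optional[HBondCriteria] = None) -> HBondTrace:
    """Evaluate the geometric criteria for every donor-acceptor pair.

    ``donors`` lists ``(donor_heavy_atom_id, hydrogen_id)`` pairs; a
    donor whose hydrogen is absent from the trajectory raises
    :class:`ConfigurationError`.
    """
    criteria = criteria or HBondCriteria()
    if not donors or not acceptors:
        raise ConfigurationError("need at least one donor and one acceptor")
    didx, hidx = [], []
    for d_id, h_id in donors:
        didx.append(traj.particles.index_of(d_id))
        try:
            hidx.append(traj.particles.index_of(h_id))
        except KeyError as exc:
            raise ConfigurationError(
                f"donor {d_id} has no hydrogen {h_id} in the trajectory") from exc
    aidx = [traj.particles.index_of(a) for a in acceptors]

    D = traj.positions[:, didx, :]          # (F, nd, 3)
    H = traj.positions[:, hidx, :]
    A = traj.positions[:, aidx, :]          # (F, na, 3)

    da = A[:, None, :, :] - D[:, :, None, :]            # (F, nd, na, 3)
    dist = np.linalg.norm(da, axis=-1)
    cos_max = np.cos(np.deg2rad(criteria.max_angle_deg))

    if criteria.angle_convention == "hda":
        dh = (H - D)[:, :, None, :]
        num = np.einsum("fdak,fdak->fda", da, dh)
        denom = dist * np.linalg.norm(dh, axis=-1)
        cos_angle = num / np.where(denom > 0, denom, np.inf)
    else:  # deviation of D-H...A from linear, measured at the hydrogen
        hd = (D - H)[:, :, None, :]
        ha = A[:, None, :, :] - H[:, :, None, :]
        num = -np.einsum("fdak,fdak->fda", hd, ha)   # cos(180 - angle_at_H)
        denom = np.linalg.norm(hd, axis=-1) * np.linalg.norm(ha, axis=-1)
        cos_angle = num / np.where(denom > 0, denom, np.inf)

    exists = (dist < criteria.max_da_distance) & (cos_angle > cos_max)
    pairs = [(int(traj.particles.ids[d]), int(traj.particles.ids[a]))
             for d in didx for a in aidx]
    dt = traj.dt if traj.dt is not None else 1.0
    return HBondTrace(pairs, exists.reshape(traj.n_frames, -1),
                      traj.times.copy(), float(dt), criteria)


@dataclass(frozen=True)
class LifetimeEstimate:
    """A lifetime in ps plus how it was obtained."""

    value_ps: float
    method: str
    n_intervals: int
    censored_only: bool = False

    @property
    def defined(self) -> bool:
        return np.isfinite(self.value_ps)

    def __float__(self) -> float:
        return float(self.value_ps)


def lifetime(trace: HBondTrace, method: str = "continuous",
             include_censored: bool = False) -> LifetimeEstimate:
    """Average hydrogen-bond lifetime from a detection trace.

    ``method="continuous"``: mean length of complete bonded intervals
    (censored first/last intervals excluded unless ``include_censored``;
    if only censored intervals exist they are used and flagged).
    ``method="survival"``: integral of the continuous-survival
    correlation, ``sum(L_i^2) / (2 sum(L_i))`` over all intervals.
    """
    ivals = trace.intervals()
    if not ivals:
        warnings.warn("no hydrogen bond was ever formed; lifetime undefined")
        return LifetimeEstimate(float("nan"), method, 0)
    lengths = np.array([iv.length_ps for iv in ivals])
    censored = np.array([iv.censored for iv in ivals])

    if method == "survival":
        return LifetimeEstimate(float(np.sum(lengths ** 2) / (2 * np.sum(lengths))),
                                method, len(ivals))
    if method != "continuous":
        raise DomainError(f"unknown lifetime method {method!r}")

    use = lengths if include_censored else lengths[~censored]
    censored_only = False
    if use.size == 0:
        # e.g. an always-on trace: report the censored span, flagged.
        use = lengths
        censored_only = True
    return LifetimeEstimate(float(np.mean(use)), method, int(use.size),
                            censored_only)
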