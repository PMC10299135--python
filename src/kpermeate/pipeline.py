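"""End-to-end analysis pipeline and condition comparison.

One validated :class:`RunConfig` in, a bundle of condition-labelled
tables out: site map, permeation summary, knock-on events and mode
proportions, residence times, PMF and occupancy, plus optional spectra
and hydrogen-bond lifetimes when the inputs support them.  All chosen
conventions and defaults are echoed into ``summary.json`` and the run
log so a bundle is self-describing; outputs are pure functions of
(inputs, config).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .errors import ConfigurationError
from .hbond import HBondCriteria, detect_hbonds, lifetime
from .knockon import detect_events, events_to_frame, mode_proportions
from .permeation import (count_crossings, percent_change, residence_times,
                         summarize_permeation)
from .pmf import axial_pmf, occupancy_rates
from .sites import assign_sites
from .spectra import peak_frequencies, power_spectrum, vacf
from .trajectory import Species, Trajectory, read_trajectory

__all__ = ["RunConfig", "run_pipeline", "compare_conditions"]

logger = logging.getLogger("kpermeate")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of one analysis run.

    Field parameters (``field_e0_vnm``, ``field_freq_thz``, ``field_t0_ps``)
    are run metadata describing the condition the trajectory was
    produced under; they do not alter the analysis.
    """

    trajectory: str
    outdir: str
    structure: Optional[str] = None
    species: Optional[Mapping[str, str]] = None
    condition: str = "run"
    site_map_mode: str = "static"
    voltage_v: Optional[float] = None
    field_e0_vnm: Optional[float] = None
    field_freq_thz: Optional[float] = None
    field_t0_ps: float = 0.0
    bin_width_a: float = 0.2
    counting: str = "net"
    mode_rule: str = "literal"
    hbond_max_distance_a: float = 3.5
    hbond_max_angle_deg: float = 30.0
    hbond_angle_convention: str = "hda"
    run_hbond: bool = False
    spectrum_window: str = "hann"
    spectrum_max_lag_ps: Optional[float] = None
    run_spectra: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        missing = {"trajectory", "outdir"} - set(raw)
        if missing:
            raise ConfigurationError(f"missing required config keys: {sorted(missing)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    """Decorator tagging failures with the pipeline stage name."""
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def _water_donor_pairs(traj: Trajectory) -> list[tuple[int, int]]:
    """Pair each water hydrogen with its nearest water oxygen (frame 0)."""
    o_cols = np.flatnonzero(traj.particles.mask(Species.WATER_O))
    h_cols = np.flatnonzero(traj.particles.mask(Species.WATER_H))
    pairs = []
    if len(o_cols) == 0 or len(h_cols) == 0:
        return pairs
    o_pos = traj.positions[0, o_cols]
    for h in h_cols:
        d = np.linalg.norm(o_pos - traj.positions[0, h], axis=1)
        o = o_cols[int(np.argmin(d))]
        pairs.append((int(traj.particles.ids[o]), int(traj.particles.ids[h])))
    return pairs


def run_pipeline(config: RunConfig,
                 trajectory: Optional[Trajectory] = None) -> dict:
    """Run all applicable stages and write the report bundle.

    Returns the machine-readable summary (also written as
    ``summary.json``).  ``trajectory`` bypasses file reading when the
    caller already holds one in memory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    summary: dict = {"condition": config.condition, "version": __version__,
                     "config": config.to_dict()}
    try:
        logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

        if trajectory is None:
            trajectory = _stage("read")(read_trajectory)(
                config.structure, config.trajectory, config.species)
        logger.info("read: %d frames, %d particles, dt=%s ps",
                    trajectory.n_frames, trajectory.n_particles, trajectory.dt)

        assign = _stage("site_assignment")(assign_sites)(
            trajectory, config.site_map_mode)
        assign.site_map.write(outdir / "site_map.csv")
        logger.info("site_assignment: %d tracked particles (%s bounds)",
                    len(assign.particle_ids), assign.mode)

        crossings = _stage("permeation")(count_crossings)(assign)
        perm = _stage("permeation")(summarize_permeation)(
            crossings, trajectory.duration, config.voltage_v,
            config.condition, config.counting)
        perm.to_frame().to_csv(outdir / "permeation_summary.csv", index=False)
        logger.info("permeation: %d outward, %d inward, net %d",
                    len(crossings.outward), len(crossings.inward), crossings.net)

        events = _stage("knockon")(detect_events)(assign, crossings,
                                                  config.mode_rule)
        props = mode_proportions(events)
        events_to_frame(events).to_csv(outdir / "events.csv", index=False)
        props.to_frame(config.condition).to_csv(outdir / "mode_proportions.csv",
                                                index=False)
        logger.info("knockon: %d events (state order S4->S0, rule=%s)",
                    len(events), config.mode_rule)

        residence = _stage("residence")(residence_times)(assign, crossings)
        residence.to_frame().to_csv(outdir / "residence.csv", index=False)

        lo, hi = assign.site_map.edges[0], assign.site_map.edges[-1]
        profile = _stage("pmf")(axial_pmf)(trajectory, (float(lo), float(hi)),
                                           config.bin_width_a)
        profile.to_frame().to_csv(outdir / "pmf.csv", index=False)
        occupancy = _stage("occupancy")(occupancy_rates)(assign)
        occupancy.to_frame().to_csv(outdir / "occupancy.csv", index=False)

        summary.update({
            "n_frames": trajectory.n_frames,
            "duration_ps": trajectory.duration,
            "crossings_net": crossings.net,
            "crossings_outward": len(crossings.outward),
            "flux_per_400ns": perm.flux_per_400ns,
            "current_pA": perm.current_pa,
            "conductance_pS": perm.conductance_ps,
            "mode_counts": {m.value: c for m, c in props.counts.items()},
            "mode_fractions": (None if not props.defined else
                               {m.value: f for m, f in props.fractions.items()}),
            "occupancy": occupancy.as_dict(),
            "residence_mean_ps": {s: (None if not residence.defined else
                                      float(v))
                                  for s, v in zip(residence.sites,
                                                  residence.mean_ps)},
        })

        if config.run_spectra:
            if trajectory.velocities is None:
                raise RuntimeError("stage 'spectra' failed: spectra requested "
                                   "but the trajectory carries no velocities")
            acf = _stage("spectra")(vacf)(trajectory.velocities, trajectory.dt,
                                          config.spectrum_max_lag_ps)
            spec = power_spectrum(acf, window=config.spectrum_window)
            spec.to_frame().to_csv(outdir / "spectrum.csv", index=False)
            summary["spectrum_peaks_thz"] = peak_frequencies(spec, n_peaks=5)

        if config.run_hbond:
            donors = _water_donor_pairs(trajectory)
            acceptors = [int(i) for i in trajectory.particles.ids[
                trajectory.particles.mask(Species.PROTEIN_REF)
                & (trajectory.particles.atom_label == "OG1")]]
            if not donors or not acceptors:
                raise RuntimeError("stage 'hbond' failed: no water donors or "
                                   "hydroxyl-oxygen acceptors in the trajectory")
            criteria = HBondCriteria(config.hbond_max_distance_a,
                                     config.hbond_max_angle_deg,
                                     config.hbond_angle_convention)
            trace = _stage("hbond")(detect_hbonds)(trajectory, donors,
                                                   acceptors, criteria)
            trace.to_frame().to_csv(outdir / "hbond_trace.csv", index=False)
            cont = lifetime(trace, "continuous")
            surv = lifetime(trace, "survival")
            pd.DataFrame([{"condition": config.condition,
                           "lifetime_continuous_ps": cont.value_ps,
                           "lifetime_survival_ps": surv.value_ps,
                           "n_intervals": cont.n_intervals}]).to_csv(
                outdir / "hbond_lifetime.csv", index=False)
            summary["hbond_lifetime_ps"] = cont.value_ps

        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        logger.info("bundle written to %s", outdir)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return summary


def compare_conditions(bundles: Mapping[str, dict | str | Path],
                       reference_label: str) -> pd.DataFrame:
    """Tabulate flux/current/conductance per condition vs a reference.

    ``bundles`` maps condition labels to pipeline summaries (dicts) or
    paths to ``summary.json`` files.  The percent change of the flux
    relative to ``reference_label`` is appended per row.
    """
    if not bundles:
        raise ConfigurationError("no bundles to compare")
    loaded = {}
    for label, bundle in bundles.items():
        if isinstance(bundle, (str, Path)):
            bundle = json.loads(Path(bundle).read_text())
        loaded[label] = bundle
    if reference_label not in loaded:
        raise ConfigurationError(f"unknown reference label {reference_label!r}")
    ref_flux = loaded[reference_label]["flux_per_400ns"]
    rows = []
    for label, s in loaded.items():
        rows.append({
            "condition": label,
            "flux_per_400ns": s["flux_per_400ns"],
            "current_pA": s.get("current_pA"),
            "conductance_pS": s.get("conductance_pS"),
            "flux_change_pct": percent_change(ref_flux, s["flux_per_400ns"]),
        })
    return pd.DataFrame(rows)
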