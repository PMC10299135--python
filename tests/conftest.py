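"""Shared fixtures: study-condition chain specs and small trajectories.

Fixture parameter values (rates, dwell constants, oscillator
frequencies) live here, not in the library.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from kpermeate.synthetic import SFMarkovSpec

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

# Hub-and-spoke loading-state chain whose every state condenses into the
# literal knock-on vocabulary.  From the hub OKKKO the chain branches to
# a pre-exit state of each mode with probabilities 0.5 / 0.3 / 0.2
# (soft / direct / mixed); every visit to a pre-exit state ends in one
# declared exit back to the hub.
MODE_HUB = "OKKKO"
MODE_BRANCHES = {"KWKWK": ("SOFT", 0.5), "OOKKK": ("DIRECT", 0.3),
                 "OKWKK": ("MIXED", 0.2)}
_BRANCH_RATE = 0.5   # 1/ps total hub exit rate
_EXIT_RATE = 1.0     # 1/ps


def mode_cycle_spec(seed: int, duration: float = 200.0, dt: float = 0.05) -> SFMarkovSpec:
    rates = {}
    exits = set()
    for state, (_, prob) in MODE_BRANCHES.items():
        rates[(MODE_HUB, state)] = _BRANCH_RATE * prob
        rates[(state, MODE_HUB)] = _EXIT_RATE
        exits.add((state, MODE_HUB))
    return SFMarkovSpec(states=(MODE_HUB,) + tuple(MODE_BRANCHES),
                        rates=rates, exit_transitions=frozenset(exits),
                        dt=dt, duration=duration, seed=seed)


# Single-file ladder: one ion hops S4 -> S3 -> ... -> S0 -> exit, each
# hop at the same rate, so the true mean dwell at every site is 1/rate.
LADDER_RATE = 0.2    # 1/ps; mean dwell 5 ps per site
_LADDER_STATES = ("KOOOO", "OKOOO", "OOKOO", "OOOKO", "OOOOK")


def ladder_spec(seed: int, n_events: float = 50, dt: float = 0.25) -> SFMarkovSpec:
    rates = {(_LADDER_STATES[i], _LADDER_STATES[(i + 1) % 5]): LADDER_RATE
             for i in range(5)}
    duration = n_events * 5 / LADDER_RATE
    return SFMarkovSpec(states=_LADDER_STATES, rates=rates,
                        exit_transitions=frozenset({(_LADDER_STATES[4],
                                                     _LADDER_STATES[0])}),
                        dt=dt, duration=duration, seed=seed)


# Exit-free two-ion rearrangement chain with a known stationary law
# pi = (1/4, 1/2, 1/4); per-site K occupancy (S4..S0) =
# (0.25, 0.75, 0.75, 0.25, 0).
OCC_STATIONARY_SITES = {"S_cav": 0.0, "S4": 0.25, "S3": 0.75,
                        "S2": 0.75, "S1": 0.25, "S0": 0.0}


def occupancy_spec(seed: int, duration: float = 5e4, dt: float = 0.25) -> SFMarkovSpec:
    return SFMarkovSpec(
        states=("KKOOO", "OKKOO", "OOKKO"),
        rates={("KKOOO", "OKKOO"): 0.4, ("OKKOO", "KKOOO"): 0.2,
               ("OKKOO", "OOKKO"): 0.2, ("OOKKO", "OKKOO"): 0.4},
        dt=dt, duration=duration, seed=seed)


@pytest.fixture
def mode_chain():
    return mode_cycle_spec(seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(20230617)
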