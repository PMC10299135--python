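"""Generators: field model, Markov chains, samplers, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpermeate.errors import ConfigurationError, DomainError
from kpermeate.synthetic import (DEFAULT_SITE_CENTERS, FieldWaveform,
                                 SFMarkovSpec, SPEED_OF_LIGHT, field_at,
                                 force_ratio, gen_boltzmann_1d, gen_crossings,
                                 gen_hbond_telegraph, gen_oscillator_velocity,
                                 gen_sf_markov, write_ground_truth)
from conftest import mode_cycle_spec


class TestFieldModel:
    def test_amplitude_at_phase_reference(self):
        w = FieldWaveform(E0=0.4, freq=15.0, t0=2.0)
        assert field_at(w, 2.0) == pytest.approx(0.4)

    def test_zero_at_quarter_period(self):
        w = FieldWaveform(E0=0.4, freq=4.0)
        assert field_at(w, 0.25 / 4.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_frequency_is_constant(self):
        w = FieldWaveform(E0=0.4, freq=0.0)
        assert field_at(w, 123.4) == pytest.approx(0.4)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
    def test_periodicity(self, freq, t):
        w = FieldWaveform(E0=1.0, freq=freq)
        assert field_at(w, t) == pytest.approx(field_at(w, t + 1.0 / freq),
                                               abs=1e-9)

    @pytest.mark.parametrize("speed,expected", [
        (0.0, 0.0),
        (SPEED_OF_LIGHT * 1e-6, 1e-6),
        (300.0, 300.0 / SPEED_OF_LIGHT),
    ])
    def test_force_ratio(self, speed, expected):
        assert force_ratio(speed) == pytest.approx(expected, rel=1e-12)

    def test_force_ratio_domain(self):
        with pytest.raises(DomainError):
            force_ratio(SPEED_OF_LIGHT)
        with pytest.raises(DomainError):
            force_ratio(-1.0)


class TestMarkovGenerator:
    def test_zero_rates_give_static_trajectory(self):
        spec = SFMarkovSpec(states=("OKKKO",), rates={}, dt=0.5,
                            duration=10.0, seed=1)
        traj, gt = gen_sf_markov(spec)
        assert len(gt.events) == 0
        assert gt.warnings  # absorbing chain is flagged, not an error
        z = traj.positions[:, :, 2]
        assert np.all(np.std(z, axis=0) < 1.0)  # only jitter moves anything

    def test_soft_only_chain_yields_soft_events(self):
        # two-state cycle whose only exits occur from KWKWK
        spec = SFMarkovSpec(
            states=("KWKWK", "KKWKO"),
            rates={("KWKWK", "KKWKO"): 0.4, ("KKWKO", "KWKWK"): 0.4},
            exit_transitions=frozenset({("KWKWK", "KKWKO")}),
            dt=0.1, duration=500.0, seed=5)
        traj, gt = gen_sf_markov(spec)
        assert len(gt.events) > 20
        assert all(e.mode == "SOFT" for e in gt.events)
        assert all(e.state_before == "KWKWK" for e in gt.events)

    def test_fixed_seed_is_bit_identical(self, mode_chain):
        t1, g1 = gen_sf_markov(mode_chain)
        t2, g2 = gen_sf_markov(mode_chain)
        assert np.array_equal(t1.positions, t2.positions)
        assert [e.frame for e in g1.events] == [e.frame for e in g2.events]

    def test_crossing_count_equals_events(self, mode_chain):
        _, gt = gen_sf_markov(mode_chain)
        assert gt.crossing_count == len(gt.events)

    def test_exit_transition_needs_k_in_s0(self):
        with pytest.raises(ConfigurationError):
            SFMarkovSpec(states=("OKKKO", "OOKKK"),
                         rates={("OKKKO", "OOKKK"): 1.0},
                         exit_transitions=frozenset({("OKKKO", "OOKKK")}))

    def test_ground_truth_serialises(self, tmp_path, mode_chain):
        _, gt = gen_sf_markov(mode_chain)
        text = write_ground_truth(gt, tmp_path / "gt.txt").read_text()
        assert "crossing_count" in text and "events:" in text


class TestBoltzmannSampler:
    def test_flat_potential_is_uniform(self):
        traj = gen_boltzmann_1d(lambda z: np.zeros_like(z), (0.0, 1.0),
                                50_000, seed=2)
        z = traj.positions[:, 0, 2]
        counts, _ = np.histogram(z, bins=10, range=(0, 1))
        # binomial 3-sigma on 10 equiprobable bins
        assert np.all(np.abs(counts - 5000) < 3 * np.sqrt(5000 * 0.9))

    def test_harmonic_variance_matches_one_over_kappa(self):
        kappa, n = 2.0, 100_000
        traj = gen_boltzmann_1d(lambda z: 0.5 * kappa * z ** 2,
                                (-5.0, 5.0), n, seed=3)
        z = traj.positions[:, 0, 2]
        se = (1.0 / kappa) * np.sqrt(2.0 / n)
        assert abs(np.var(z) - 1.0 / kappa) < 3 * se

    def test_zero_samples_gives_empty_trajectory(self):
        assert gen_boltzmann_1d(lambda z: z * 0, (0, 1), 0, seed=0).n_frames == 0


class TestOscillator:
    def test_pure_cosine(self):
        t, v = gen_oscillator_velocity(15.0, 0.004, 1.0)
        np.testing.assert_allclose(v, np.cos(2 * np.pi * 15.0 * t), atol=1e-12)
        assert np.max(np.abs(v)) == pytest.approx(1.0)
        assert len(v) == 250

    def test_zero_frequency_is_constant(self):
        _, v = gen_oscillator_velocity(0.0, 0.01, 1.0)
        np.testing.assert_allclose(v, 1.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(DomainError):
            gen_oscillator_velocity(15.0, 0.04, 1.0)  # Nyquist is 12.5 THz


class TestTelegraph:
    def test_mean_on_dwell_matches_tau(self):
        tau = 20.0
        _, gt = gen_hbond_telegraph(tau, 10.0, dt=0.5,
                                    duration=4000 * 30.0, seed=4)
        dwells = gt.on_dwells[:-1]   # last interval truncated at the end
        assert len(dwells) > 500
        assert abs(np.mean(dwells) - tau) / tau < 0.05

    def test_infinite_tau_off_single_interval(self):
        traj, gt = gen_hbond_telegraph(1e9, np.inf, dt=1.0, duration=100.0,
                                       seed=0)
        assert len(gt.on_intervals) == 1
        assert gt.on_intervals[0] == (0.0, 100.0)

    def test_fixed_seed_identical_intervals(self):
        _, g1 = gen_hbond_telegraph(5.0, 5.0, 0.1, 1000.0, seed=9)
        _, g2 = gen_hbond_telegraph(5.0, 5.0, 0.1, 1000.0, seed=9)
        assert g1.on_intervals == g2.on_intervals


class TestScheduledCrossings:
    def test_monotone_transits(self):
        traj = gen_crossings([30.0, 60.0], duration=100.0, dt=0.5)
        z = traj.positions[:, :2, 2]
        assert np.all(np.diff(z, axis=0) >= 0)
        assert z[0, 0] < DEFAULT_SITE_CENTERS[0]
        assert z[-1, 0] > DEFAULT_SITE_CENTERS[-1]

    def test_schedule_outside_duration_rejected(self):
        with pytest.raises(DomainError):
            gen_crossings([99.0], duration=100.0, dt=0.5, transit_ps=10.0)

    def test_empty_schedule(self):
        traj = gen_crossings([], duration=10.0, dt=0.5)
        assert traj.particles.mask("K").sum() == 0
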