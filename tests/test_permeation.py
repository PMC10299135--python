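"""Transit counting, flux/current arithmetic, residence times."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kpermeate.errors import DomainError
from kpermeate.permeation import (ELEMENTARY_CHARGE, count_crossings,
                                  percent_change, residence_times,
                                  summarize_permeation,
                                  _transits_for_labels)
from kpermeate.sites import (LABEL_NAMES, OUTSIDE_ABOVE, OUTSIDE_BELOW, S_CAV,
                             SiteAssignment, SiteMap, assign_sites)
from kpermeate.synthetic import gen_crossings, gen_sf_markov
from kpermeate.trajectory import Species
from conftest import LADDER_RATE, ladder_spec


def assignment_from_labels(label_rows, species=("K",)):
    """SiteAssignment with an explicit label matrix (frames x particles)."""
    labels = np.asarray(label_rows, dtype=np.uint8)
    n = labels.shape[1]
    return SiteAssignment(
        particle_ids=np.arange(n), species=np.array(list(species) * n,
                                                    dtype=object)[:n],
        labels=labels, times=np.arange(labels.shape[0], dtype=float),
        dt=1.0, site_map=SiteMap(np.arange(-3.0, 4.0)))


class TestCounting:
    def test_scheduled_crossings_are_all_counted(self):
        traj = gen_crossings(list(np.linspace(20, 380, 37)), 400.0, 0.5)
        result = count_crossings(assign_sites(traj))
        assert result.net == 37
        assert len(result.outward) == 37 and len(result.inward) == 0

    def test_s0_boundary_oscillation_is_not_a_transit(self):
        S0 = LABEL_NAMES.index("S0")
        labels = [[S0], [OUTSIDE_ABOVE], [S0], [OUTSIDE_ABOVE], [S0]]
        result = count_crossings(assignment_from_labels(labels))
        assert result.net == 0

    def test_cavity_arms_the_counter(self):
        labels = [[S_CAV], [LABEL_NAMES.index("S2")], [OUTSIDE_ABOVE]]
        assert count_crossings(assignment_from_labels(labels)).net == 1

    def test_round_trip_cancels(self):
        labels = [[OUTSIDE_BELOW], [OUTSIDE_ABOVE], [OUTSIDE_BELOW]]
        result = count_crossings(assignment_from_labels(labels))
        assert result.net == 0
        assert len(result.outward) == len(result.inward) == 1

    def test_time_reversal_negates_net_count(self):
        traj = gen_crossings([30.0, 50.0, 70.0], 100.0, 0.5)
        forward = count_crossings(assign_sites(traj))
        backward = count_crossings(assign_sites(traj.time_reversed()))
        assert backward.net == -forward.net == -3

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, len(LABEL_NAMES) - 1), min_size=1,
                    max_size=30))
    def test_reversal_antisymmetry_on_arbitrary_label_paths(self, labels):
        seq = np.asarray(labels, dtype=np.uint8)
        out_f, in_f = _transits_for_labels(seq)
        out_b, in_b = _transits_for_labels(seq[::-1])
        assert (len(out_f) - len(in_f)) == -(len(out_b) - len(in_b))


class TestSummary:
    def test_zero_crossings(self):
        s = summarize_permeation(0, 400_000.0)
        assert s.flux_per_400ns == 0.0 and s.current_pa == 0.0

    def test_current_formula(self):
        s = summarize_permeation(25, 400_000.0)
        assert s.current_pa == pytest.approx(10.0136, abs=1e-4)
        # exact double-precision identity
        assert s.current_pa == 25 * ELEMENTARY_CHARGE / 400e-9 * 1e12

    def test_current_is_linear_in_count_and_inverse_in_time(self):
        base = summarize_permeation(10, 1e5).current_pa
        assert summarize_permeation(20, 1e5).current_pa == 2 * base
        assert summarize_permeation(10, 2e5).current_pa == base / 2

    def test_conductance_needs_nonzero_voltage(self):
        s = summarize_permeation(31, 400_000.0, voltage=0.48)
        assert s.conductance_ps == pytest.approx(s.current_pa / 0.48)
        with pytest.raises(DomainError):
            summarize_permeation(31, 400_000.0, voltage=0.0)

    @pytest.mark.parametrize("ref,value,expected", [
        (31, 52, 67.7), (10, 10, 0.0), (10, 5, -50.0),
    ])
    def test_percent_change(self, ref, value, expected):
        assert round(percent_change(ref, value), 1) == expected

    def test_percent_change_zero_reference(self):
        with pytest.raises(DomainError):
            percent_change(0, 5)


class TestResidence:
    def test_single_permeating_ion(self):
        S2 = LABEL_NAMES.index("S2")
        path = [[OUTSIDE_BELOW]] + [[S2]] * 10 + [[OUTSIDE_ABOVE]]
        assign = assignment_from_labels(path)
        assign.dt = 2.0
        crossings = count_crossings(assign)
        table = residence_times(assign, crossings)
        assert table.mean("S2") == pytest.approx(20.0)
        assert table.n_permeating == 1

    def test_mean_divides_by_permeating_count(self):
        S3 = LABEL_NAMES.index("S3")
        rows = [[OUTSIDE_BELOW, OUTSIDE_BELOW]] + [[S3, S3]] * 30 + \
            [[OUTSIDE_ABOVE, OUTSIDE_ABOVE]]
        assign = assignment_from_labels(rows, species=("K", "K"))
        table = residence_times(assign, count_crossings(assign))
        assert table.total("S3") == pytest.approx(60.0)
        assert table.mean("S3") == pytest.approx(30.0)

    def test_zero_permeating_ions_flagged(self):
        S2 = LABEL_NAMES.index("S2")
        assign = assignment_from_labels([[S2]] * 5)
        table = residence_times(assign, count_crossings(assign))
        assert not table.defined
        assert table.total("S2") == pytest.approx(5.0)
        assert np.isnan(table.mean("S2"))

    def test_dwell_totals_conserve_in_filter_time(self):
        traj, _ = gen_sf_markov(ladder_spec(seed=8, n_events=20))
        assign = assign_sites(traj)
        table = residence_times(assign, count_crossings(assign))
        k_labels = assign.labels[:, assign.k_columns]
        inside = np.count_nonzero((k_labels >= 1) & (k_labels <= 6))
        assert table.total_ps.sum() == pytest.approx(inside * assign.dt)

    def test_markov_exit_rate_recovery(self):
        # aggregate replicas; mean dwell of permeating ions ~ 1/rate
        totals = np.zeros(6)
        n_perm = 0
        for seed in range(12):
            traj, _ = gen_sf_markov(ladder_spec(seed=100 + seed, n_events=50))
            assign = assign_sites(traj)
            crossings = count_crossings(assign)
            table = residence_times(assign, crossings, only_permeating=True)
            totals += table.total_ps
            n_perm += crossings.n_permeating
        assert n_perm >= 400
        means = totals / n_perm
        expected = 1.0 / LADDER_RATE
        for i, site in enumerate(("S4", "S3", "S2", "S1", "S0")):
            assert means[i + 1] == pytest.approx(expected, rel=0.05), site

    def test_concatenation_adds_counts_and_dwells(self):
        # additivity holds when the junction does not itself cross the
        # pore: the second segment starts on the side the first ended on
        S2 = LABEL_NAMES.index("S2")
        S0 = LABEL_NAMES.index("S0")
        part_a = [[OUTSIDE_BELOW]] + [[S2]] * 4 + [[OUTSIDE_ABOVE]]
        part_b = [[OUTSIDE_ABOVE], [S0], [S2], [S2], [OUTSIDE_ABOVE]]
        one = assignment_from_labels(part_a)
        two = assignment_from_labels(part_b)
        both = assignment_from_labels(part_a + part_b)
        ca, cb, c2 = count_crossings(one), count_crossings(two), \
            count_crossings(both)
        assert c2.net == ca.net + cb.net == 1
        ra = residence_times(one, ca)
        rb = residence_times(two, cb)
        r2 = residence_times(both, c2)
        assert r2.total("S2") == pytest.approx(ra.total("S2")
                                               + rb.total("S2"))
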