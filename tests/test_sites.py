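"""Site-map construction, assignment partition, pore diameters."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from kpermeate.errors import ConfigurationError
from kpermeate.sites import (LABEL_NAMES, REFERENCE_ATOMS, SITE_NAMES,
                             SiteMap, assign_sites, build_site_map,
                             pore_diameter)
from kpermeate.trajectory import Particles, Species, Trajectory


def scaffold_trajectory(ring_z, extra_rows=(), extra_pos=(), n_frames=1,
                        chains=("A", "B", "C", "D"), ring_spread=0.0,
                        shuffle_seed=None):
    """Trajectory holding the six reference-oxygen rings plus extras."""
    xy = [(2.0, 0.0), (0.0, 2.0), (-2.0, 0.0), (0.0, -2.0)]
    rows, pos = [], []
    pid = 1000
    offsets = np.linspace(-ring_spread, ring_spread, len(chains))
    for j, (residue, atom) in enumerate(REFERENCE_ATOMS):
        for (x, y), chain, off in zip(xy, chains, offsets):
            rows.append((pid, Species.PROTEIN_REF.value, residue, atom, chain))
            pos.append((x, y, ring_z[j] + off))
            pid += 1
    rows = list(extra_rows) + rows
    pos = list(extra_pos) + pos
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(rows))
        rows = [rows[i] for i in order]
        pos = [pos[i] for i in order]
    particles = Particles.build(rows)
    positions = np.tile(np.asarray(pos, dtype=float)[None], (n_frames, 1, 1))
    return Trajectory(particles, np.arange(n_frames, dtype=float), positions)


class TestBuildSiteMap:
    def test_unit_spaced_rings(self):
        traj = scaffold_trajectory([0, 1, 2, 3, 4, 5])
        sm = build_site_map(traj.frame(0))
        assert sm.bounds("S4") == (0.0, 1.0)
        assert sm.bounds("S3") == (1.0, 2.0)
        assert sm.bounds("S2") == (2.0, 3.0)
        assert sm.bounds("S1") == (3.0, 4.0)
        assert sm.bounds("S0") == (4.0, 5.0)
        assert sm.bounds("S_cav") == (-3.0, 0.0)   # 0.3 nm below the hydroxyl ring

    def test_chain_averaging(self):
        traj = scaffold_trajectory([0, 1, 2, 3, 4, 5], ring_spread=0.2)
        sm = build_site_map(traj.frame(0))
        np.testing.assert_allclose(sm.edges[1:], [0, 1, 2, 3, 4, 5], atol=1e-12)

    def test_input_order_irrelevant(self):
        a = build_site_map(scaffold_trajectory([0, 1, 2, 3, 4, 5]).frame(0))
        b = build_site_map(scaffold_trajectory([0, 1, 2, 3, 4, 5],
                                               shuffle_seed=4).frame(0))
        np.testing.assert_allclose(a.edges, b.edges)

    def test_missing_ring_names_the_residue(self):
        traj = scaffold_trajectory([0, 1, 2, 3, 4, 5])
        keep = ~((traj.particles.residue_label == "376GLY")
                 & (traj.particles.atom_label == "O"))
        broken = Trajectory(
            Particles(traj.particles.ids[keep], traj.particles.species[keep],
                      traj.particles.residue_label[keep],
                      traj.particles.atom_label[keep],
                      traj.particles.chain_id[keep]),
            traj.times, traj.positions[:, keep, :])
        with pytest.raises(ConfigurationError, match="376GLY"):
            build_site_map(broken.frame(0))


class TestAssignment:
    def ion_traj(self, zs):
        rows = [(i, Species.K.value, "", "K", "") for i in range(len(zs))]
        pos = [(0.0, 0.0, z) for z in zs]
        return scaffold_trajectory([0, 1, 2, 3, 4, 5], rows, pos)

    def test_boundary_goes_to_upper_site(self):
        assign = assign_sites(self.ion_traj([2.0]))
        assert LABEL_NAMES[assign.labels[0, 0]] == "S2"

    def test_site_centers(self):
        assign = assign_sites(self.ion_traj([2.5, -1.0, 7.0, -5.0]))
        names = [LABEL_NAMES[c] for c in assign.labels[0]]
        assert names == ["S2", "S_cav", "OUTSIDE_ABOVE", "OUTSIDE_BELOW"]

    def test_water_above_filter(self):
        traj = scaffold_trajectory([0, 1, 2, 3, 4, 5],
                                   [(0, Species.WATER_O.value, "", "OW", "")],
                                   [(0.0, 0.0, 9.0)])
        assign = assign_sites(traj)
        assert LABEL_NAMES[assign.labels[0, 0]] == "OUTSIDE_ABOVE"

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-20, 20), min_size=1, max_size=8),
           st.integers(-50, 50))
    def test_partition_and_translation_invariance(self, zs, shift):
        # keep samples clearly off the (integer) boundaries so that float
        # rounding of the common shift cannot flip a half-open comparison
        assume(all(abs(z - round(z)) > 1e-6 for z in zs))
        assign = assign_sites(self.ion_traj(zs))
        assert assign.labels.shape == (1, len(zs))
        assert np.all((assign.labels >= 0) & (assign.labels < len(LABEL_NAMES)))

        shifted = self.ion_traj(zs)
        shifted.positions[..., 2] += shift
        assign2 = assign_sites(shifted)
        np.testing.assert_array_equal(assign.labels, assign2.labels)
        np.testing.assert_allclose(assign2.site_map.edges,
                                   assign.site_map.edges + shift, atol=1e-9)

    def test_per_frame_mode_matches_static_for_rigid_scaffold(self):
        traj = scaffold_trajectory([0, 1, 2, 3, 4, 5],
                                   [(0, Species.K.value, "", "K", "")],
                                   [(0.0, 0.0, 2.5)], n_frames=3)
        static = assign_sites(traj, "static")
        per_frame = assign_sites(traj, "per_frame")
        np.testing.assert_array_equal(static.labels, per_frame.labels)

    def test_gap_free_contiguous_intervals(self):
        sm = build_site_map(scaffold_trajectory([0, 1, 2, 3, 4, 5]).frame(0))
        np.testing.assert_allclose(sm.upper[:-1], sm.lower[1:])


class TestPoreDiameter:
    def test_cross_geometry(self):
        traj = scaffold_trajectory([0, 1, 2, 3, 4, 5])
        d = pore_diameter(traj, "377TYR")
        assert d.shape == (1,)
        assert d[0] == pytest.approx(4.0)   # rings sit on a 2 A radius

    def test_square_diagonal(self):
        # oxygens of one residue on a square of side s: diagonal = s*sqrt(2)
        s = 3.0
        half = s / 2
        xy = [(half, half), (-half, half), (-half, -half), (half, -half)]
        rows = [(i, Species.PROTEIN_REF.value, "375VAL", "O", c)
                for i, c in enumerate("ABCD")]
        pos = [(x, y, 0.0) for x, y in xy]
        traj = Trajectory(Particles.build(rows), np.array([0.0]),
                          np.asarray(pos)[None])
        assert pore_diameter(traj, "375VAL")[0] == pytest.approx(s * np.sqrt(2))

    def test_requires_four_chains(self):
        traj = scaffold_trajectory([0, 1, 2, 3, 4, 5], chains=("A", "A", "B", "C"))
        with pytest.raises(ConfigurationError):
            pore_diameter(traj, "375VAL")
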