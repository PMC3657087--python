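"""Hydrogen-bond geometry, virtual hydrogens, distance statistics."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glycotraj.interactions import (HBondSpec, atom_sites, average_tables,
                                    cross_hbond_spec, detect_hbonds,
                                    distance_series, fraction_below,
                                    histogram, occupancy_table,
                                    place_virtual_hydrogen, resolve_sites,
                                    virtual_site)
from glycotraj.model_io import (AtomRecord, Frame, FrameStream, Residue,
                                Selection, Topology, select)


def _methylidyne_topology():
    """One united CH carbon bonded to three heavy neighbors."""
    atoms = [AtomRecord("C1", "C", 13.019, is_united_carbon=True),
             AtomRecord("C2", "C", 12.011), AtomRecord("C3", "C", 12.011),
             AtomRecord("O1", "O", 15.999)]
    top = Topology(atoms, [Residue("LIG", 1, "A", 0, 4)],
                   [(0, 1), (0, 2), (0, 3)])
    return top


def _tetrahedral_frame():
    # three neighbors along ideal tetrahedral directions from the carbon
    dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1]]) / math.sqrt(3)
    coords = np.vstack([[0.0, 0.0, 0.0], dirs * 0.15])
    return Frame(coords)


class TestVirtualHydrogen:
    def test_ideal_tetrahedral_completion(self):
        top = _methylidyne_topology()
        frame = _tetrahedral_frame()
        h = place_virtual_hydrogen(0, frame, top, bond_length=0.1)
        # the exact fourth tetrahedral corner
        np.testing.assert_allclose(h / np.linalg.norm(h),
                                   np.array([-1, -1, 1]) / math.sqrt(3),
                                   atol=1e-12)
        for k in range(1, 4):
            v1 = h - frame.coordinates[0]
            v2 = frame.coordinates[k] - frame.coordinates[0]
            ang = math.degrees(math.acos(
                v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
            assert ang == pytest.approx(109.4712, abs=0.01)

    def test_bond_length_exact(self):
        top = _methylidyne_topology()
        frame = _tetrahedral_frame()
        for bl in (0.1, 0.109):
            h = place_virtual_hydrogen(0, frame, top, bond_length=bl)
            assert np.linalg.norm(h - frame.coordinates[0]) == \
                pytest.approx(bl, abs=1e-12)

    def test_commutes_with_rigid_motion(self):
        top = _methylidyne_topology()
        rng = np.random.default_rng(0)
        coords = _tetrahedral_frame().coordinates + rng.normal(0, 0.01, (4, 3))
        h0 = place_virtual_hydrogen(0, Frame(coords), top)
        rot = Rotation.random(random_state=1).as_matrix()
        t = np.array([0.3, -1.0, 2.0])
        h1 = place_virtual_hydrogen(0, Frame(coords @ rot.T + t), top)
        np.testing.assert_allclose(h1, h0 @ rot.T + t, atol=1e-12)

    def test_matches_grid_search_oracle_on_distorted_geometry(self):
        """On a slightly distorted center the tetrahedral-completion
        direction agrees with a 1-degree brute-force sphere search for the
        direction of most-equal angles to the three neighbors.  (The two
        constructions coincide only to first order in the distortion, so
        the comparison uses a small perturbation.)"""
        top = _methylidyne_topology()
        rng = np.random.default_rng(2)
        coords = _tetrahedral_frame().coordinates.copy()
        coords[1:] += rng.normal(0, 0.001, (3, 3))
        frame = Frame(coords)
        h = place_virtual_hydrogen(0, frame, top)
        u_impl = h / np.linalg.norm(h)

        units = np.array([c / np.linalg.norm(c) for c in coords[1:]])
        theta = np.radians(np.arange(0.5, 180, 1.0))
        phi = np.radians(np.arange(0.5, 360, 1.0))
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                         np.cos(tt)], axis=-1).reshape(-1, 3)
        # the angle-spread objective is antipode-symmetric; restrict to the
        # hemisphere facing away from the neighbors
        dirs = dirs[dirs @ u_impl > 0]
        angles = np.degrees(np.arccos(np.clip(dirs @ units.T, -1, 1)))
        spread = angles.max(axis=1) - angles.min(axis=1)
        u_grid = dirs[np.argmin(spread)]
        ang = math.degrees(math.acos(np.clip(u_impl @ u_grid, -1, 1)))
        assert ang < 2.0  # within grid resolution

    def test_wrong_neighbor_count_rejected(self):
        atoms = [AtomRecord("C1", "C", 13.019, is_united_carbon=True),
                 AtomRecord("C2", "C", 12.011)]
        top = Topology(atoms, [Residue("LIG", 1, "A", 0, 2)], [(0, 1)])
        with pytest.raises(ValueError, match="3"):
            place_virtual_hydrogen(0, Frame(np.zeros((2, 3)) + [[0], [1]]), top)

    def test_degenerate_planar_arrangement_rejected(self):
        top = _methylidyne_topology()
        # neighbors at 120 degrees in a plane: unit vectors sum to zero
        ang = np.radians([0, 120, 240])
        coords = np.vstack([[0, 0, 0],
                            np.column_stack([np.cos(ang), np.sin(ang),
                                             np.zeros(3)]) * 0.15])
        with pytest.raises(ValueError, match="degenerate"):
            place_virtual_hydrogen(0, Frame(coords), top)


def _hbond_frame(d_ha, angle_deg):
    """Donor O, its H, and an acceptor with prescribed H-acceptor distance
    (exact for dyadic values: the acceptor sits on the x axis from H) and
    donor-hydrogen-acceptor angle."""
    h = np.zeros(3)
    acceptor = np.array([d_ha, 0.0, 0.0])
    theta = math.radians(angle_deg)
    donor = 0.1 * np.array([math.cos(theta), math.sin(theta), 0.0])
    return Frame(np.vstack([donor, h, acceptor]))


@pytest.fixture
def hbond_topology():
    atoms = [AtomRecord("OG", "O", 15.999), AtomRecord("HG", "H", 1.008),
             AtomRecord("O", "O", 15.999)]
    return Topology(atoms, [Residue("SER", 1, "A", 0, 2),
                            Residue("GLY", 2, "A", 2, 3)], [(0, 1)])


class TestHBondCriterion:
    @pytest.mark.parametrize("d_ha,angle,present", [
        (0.24, 150.0, True),    # inside both criteria
        (0.26, 180.0, False),   # distance fails
        (0.20, 130.0, False),   # angle fails
        (0.25, 180.0, False),   # exactly at distance cutoff: strict
    ])
    def test_boundary_geometries(self, hbond_topology, d_ha, angle, present):
        spec = HBondSpec(donors=[(0, 1)], acceptors=[2])
        found = detect_hbonds(_hbond_frame(d_ha, angle), spec, hbond_topology)
        assert bool(found) is present

    def test_angle_measured_at_hydrogen_vertex(self, hbond_topology):
        frame = _hbond_frame(0.20, 150.0)
        v1 = frame.coordinates[0] - frame.coordinates[1]
        v2 = frame.coordinates[2] - frame.coordinates[1]
        ang = math.degrees(math.acos(
            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert ang == pytest.approx(150.0, abs=1e-9)

    def test_detection_invariant_under_rigid_motion(self, hbond_topology):
        spec = HBondSpec(donors=[(0, 1)], acceptors=[2])
        frame = _hbond_frame(0.24, 150.0)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = Frame(frame.coordinates @ rot.T + np.array([1.0, 2.0, -3.0]))
        assert detect_hbonds(frame, spec, hbond_topology) == \
            detect_hbonds(moved, spec, hbond_topology)

    def test_unbonded_hydrogen_rejected_by_spec(self, hbond_topology):
        spec = HBondSpec(donors=[(0, 2)], acceptors=[1])
        with pytest.raises(ValueError, match="not bonded"):
            spec.validate(hbond_topology)


class TestDistanceStatistics:
    def test_static_pair_constant_series(self, hbond_topology):
        coords = np.zeros((3, 3))
        coords[2] = [0.3, 0, 0]
        stream = FrameStream.from_array(np.array([coords] * 4))
        a = Selection("a", np.array([0]))
        b = Selection("b", np.array([2]))
        series = distance_series(stream, a, b, hbond_topology)
        np.testing.assert_allclose(series.values, 0.3, atol=1e-12)

    def test_min_over_a_takes_closest(self, hbond_topology):
        coords = np.zeros((3, 3))
        coords[0] = [0.28, 0, 0]
        coords[1] = [0.35, 0, 0]
        stream = FrameStream.from_array(coords[None])
        series = distance_series(stream, Selection("a", np.array([0, 1])),
                                 Selection("b", np.array([2])),
                                 hbond_topology, mode="min_over_a")
        assert series.values[0] == pytest.approx(0.28)

    def test_fraction_below_strict_inequality(self):
        from glycotraj.interactions import DistanceSeries
        exact = DistanceSeries("x", np.arange(4.0), np.full(4, 0.3))
        assert fraction_below(exact, 0.3) == 0.0
        below = DistanceSeries("x", np.arange(4.0), np.full(4, 0.2))
        assert fraction_below(below, 0.3) == 1.0

    def test_fraction_below_uniform_analytic(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.2, 0.4, size=10_000)
        frac = fraction_below(values, 0.3)
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_fraction_below_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0.1, 0.5, size=1000)
        cuts = np.linspace(0.05, 0.55, 20)
        fracs = [fraction_below(values, c) for c in cuts]
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))

    def test_histogram_constant_series_single_bin(self):
        h = histogram(np.full(100, 0.3012), bin_width=0.005)
        assert np.count_nonzero(h.density) == 1
        assert h.density.max() == pytest.approx(1 / 0.005)

    def test_histogram_integrates_to_one(self):
        rng = np.random.default_rng(6)
        h = histogram(rng.normal(1.0, 0.1, size=5000), bin_width=0.005)
        widths = np.diff(h.bin_edges)
        assert np.sum(h.density * widths) == pytest.approx(1.0, abs=1e-9)

    def test_histogram_matches_analytic_normal_density(self):
        rng = np.random.default_rng(7)
        x = rng.normal(1.0, 0.05, size=100_000)
        h = histogram(x, bin_width=0.005)
        centers = 0.5 * (h.bin_edges[:-1] + h.bin_edges[1:])
        analytic = np.exp(-(centers - 1.0) ** 2 / (2 * 0.05 ** 2)) \
            / (0.05 * math.sqrt(2 * math.pi))
        assert np.max(np.abs(h.density - analytic)) <= 0.05 * analytic.max()

    def test_bin_edges_aligned_to_bin_width(self):
        h = histogram(np.array([0.2931, 0.3052, 0.3174]), bin_width=0.005)
        assert np.allclose(h.bin_edges / 0.005,
                           np.round(h.bin_edges / 0.005), atol=1e-9)


class TestOccupancy:
    def test_persistent_bond_scores_100(self, hbond_topology):
        frame = _hbond_frame(0.20, 180.0)
        stream = FrameStream.from_array(
            np.repeat(frame.coordinates[None], 10, axis=0))
        spec = HBondSpec(donors=[(0, 1)], acceptors=[2])
        table = occupancy_table(stream, spec, hbond_topology,
                                Selection("lig", np.array([0, 1])))
        assert len(table.rows) == 1
        assert table.rows[0].percentage == pytest.approx(100.0)
        assert table.total == pytest.approx(100.0)

    def test_two_atom_pairs_sum_past_100(self, two_pose, two_pose_selections):
        """A partner bound through two simultaneous donor/acceptor pairs
        accumulates both, reproducing >100% occupancy rows."""
        spec, top, stream, truth = two_pose
        lig = two_pose_selections["ligand"]
        env = Selection("env", np.setdiff1d(np.arange(top.n_atoms),
                                            lig.indices))
        hspec = cross_hbond_spec(top, lig, env)
        table = occupancy_table(stream, hspec, top, lig)
        rows = {r.partner: r for r in table.rows}
        assert rows["Val-511"].percentage > 100.0
        assert set(rows["Val-511"].ligand_atoms) == {"O1", "O2"}

    def test_recovers_generator_truth(self, two_pose, two_pose_selections):
        spec, top, stream, truth = two_pose
        lig = two_pose_selections["ligand"]
        env = Selection("env", np.setdiff1d(np.arange(top.n_atoms),
                                            lig.indices))
        table = occupancy_table(stream, cross_hbond_spec(top, lig, env),
                                top, lig)
        rows = {r.partner: r.percentage for r in table.rows}
        for partner, expected in truth["occupancy"].items():
            assert rows[partner] == pytest.approx(expected, abs=3.0)

    def test_average_tables_is_arithmetic_mean(self, hbond_topology):
        from glycotraj.interactions import OccupancyRow, OccupancyTable
        t1 = OccupancyTable([OccupancyRow("Val-511", 511, 80.0, ("O1",))])
        t2 = OccupancyTable([OccupancyRow("Val-511", 511, 100.0, ("O1",)),
                             OccupancyRow("Gln-392", 392, 30.0, ("O2",))])
        mean = average_tables([t1, t2])
        rows = {r.partner: r.percentage for r in mean.rows}
        assert rows["Val-511"] == pytest.approx(90.0)
        assert rows["Gln-392"] == pytest.approx(15.0)  # absent run counts 0
        assert mean.total == pytest.approx(105.0)


class TestVirtualSiteResolution:
    def test_hc_names_resolve_to_virtual_sites(self, two_pose):
        _, top, _, _ = two_pose
        sites = resolve_sites(["HC1", "HC2", "O1"], top, resname="GLC")
        assert sites[0].virtual and sites[1].virtual
        assert not sites[2].virtual

    def test_two_pose_hc2_fraction_matches_pose_fraction(self, two_pose,
                                                         two_pose_selections):
        spec, top, stream, truth = two_pose
        hc2 = resolve_sites(["HC2"], top, resname="GLC")
        n5 = atom_sites(two_pose_selections["n5"], top)
        series = distance_series(stream, hc2, n5, top)
        assert fraction_below(series, 0.3) == \
            pytest.approx(truth["fraction_below"]["HC2-N5"], abs=0.02)
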