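"""Reaction-field/Lennard-Jones pair energies and block-averaged errors."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from glycotraj.energetics import (COULOMB_CONSTANT, EnergyEstimate,
                                  NonbondedParams, block_average,
                                  combine_runs, pair_energies,
                                  reaction_field_constant)
from glycotraj.model_io import AtomRecord, Frame, Residue, Selection, Topology
from glycotraj.synthetic import gen_ar1_series


def _ion_pair_topology(q1=1.0, q2=1.0, c6=0.0, c12=0.0):
    atoms = [AtomRecord("A1", "NA", 22.99, q1, c6, c12),
             AtomRecord("A2", "NA", 22.99, q2, c6, c12)]
    return Topology(atoms, [Residue("ION", 1, "A", 0, 1),
                            Residue("ION", 2, "A", 1, 2)])


def _random_system(n, seed, box=None):
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n):
        atoms.append(AtomRecord(f"X{i}", "C", 12.0,
                                charge=rng.uniform(-0.5, 0.5),
                                lj_c6=rng.uniform(0, 5e-3),
                                lj_c12=rng.uniform(0, 1e-5)))
    residues = [Residue("LIG", 1, "A", 0, n // 2),
                Residue("ENV", 2, "A", n // 2, n)]
    top = Topology(atoms, residues)
    # jittered grid keeps pairs >= 0.25 nm apart so r^-12 terms do not
    # magnify round-off in the brute-force comparison
    side = int(math.ceil(n ** (1 / 3)))
    grid = np.array(np.meshgrid(*[np.arange(side) * 0.43] * 3,
                                indexing="ij")).reshape(3, -1).T[:n]
    coords = grid + rng.uniform(-0.09, 0.09, size=(n, 3))
    return top, Frame(coords, box=box)


def _brute_force(frame, il, js, top, params):
    """Plain double loop over all cross pairs, no vectorization."""
    crf = reaction_field_constant(params.eps_rf)
    rc = params.cutoff
    v_es = v_vdw = 0.0
    for i in il:
        for j in js:
            d = frame.coordinates[i] - frame.coordinates[j]
            if frame.box is not None:
                d = d - frame.box * np.round(d / frame.box)
            r2 = float(d @ d)
            if not r2 < rc * rc:
                continue
            r = math.sqrt(r2)
            qq = top.atoms[i].charge * top.atoms[j].charge
            v_es += COULOMB_CONSTANT * qq * (
                1 / r + crf * r * r / (2 * rc ** 3) - (1 + crf / 2) / rc)
            c6 = math.sqrt(top.atoms[i].lj_c6 * top.atoms[j].lj_c6)
            c12 = math.sqrt(top.atoms[i].lj_c12 * top.atoms[j].lj_c12)
            v_vdw += c12 / r ** 12 - c6 / r ** 6
    return v_es, v_vdw


class TestPairEnergies:
    def test_two_charges_hand_value(self):
        """f(1/r - 1/Rc) for unit charges at 0.5 nm with eps_rf = 1."""
        top = _ion_pair_topology()
        frame = Frame([[0, 0, 0], [0.5, 0, 0]])
        v_es, v_vdw = pair_energies(frame, Selection("l", [0]),
                                    Selection("s", [1]), top,
                                    NonbondedParams(cutoff=1.4, eps_rf=1.0))
        assert v_es == pytest.approx(138.9355 * (1 / 0.5 - 1 / 1.4), rel=1e-9)
        assert v_vdw == 0.0

    def test_beyond_cutoff_is_zero(self):
        top = _ion_pair_topology(c6=1e-3, c12=1e-6)
        frame = Frame([[0, 0, 0], [1.4, 0, 0]])
        assert pair_energies(frame, Selection("l", [0]), Selection("s", [1]),
                             top) == (0.0, 0.0)

    def test_lj_zero_crossing_exact(self):
        c6, c12 = 2.3e-3, 1.5e-6
        top = _ion_pair_topology(q1=0.0, q2=0.0, c6=c6, c12=c12)
        r0 = (c12 / c6) ** (1 / 6)
        frame = Frame([[0, 0, 0], [r0, 0, 0]])
        _, v_vdw = pair_energies(frame, Selection("l", [0]),
                                 Selection("s", [1]), top)
        assert v_vdw == pytest.approx(0.0, abs=1e-12)

    def test_eps_infinity_limit(self):
        assert reaction_field_constant(1.0) == 0.0
        assert reaction_field_constant(1e12) == pytest.approx(1.0, abs=1e-11)
        assert reaction_field_constant(61.0) == pytest.approx(120 / 123)

    @pytest.mark.parametrize("box", [None, np.array([2.2, 2.2, 2.2])])
    def test_matches_brute_force_double_loop(self, box):
        top, frame = _random_system(120, seed=8, box=box)
        il = list(range(60))
        js = list(range(60, 120))
        params = NonbondedParams()
        got = pair_energies(frame, Selection("l", il), Selection("s", js),
                            top, params)
        want = _brute_force(frame, il, js, top, params)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_group_swap_and_rigid_motion_invariance(self):
        top, frame = _random_system(40, seed=9)
        l = Selection("l", list(range(20)))
        s = Selection("s", list(range(20, 40)))
        v1 = pair_energies(frame, l, s, top)
        v2 = pair_energies(frame, s, l, top)
        np.testing.assert_allclose(v1, v2, atol=1e-10)
        rot = Rotation.random(random_state=10).as_matrix()
        moved = Frame(frame.coordinates @ rot.T + np.array([3.0, -1.0, 2.0]))
        np.testing.assert_allclose(pair_energies(moved, l, s, top), v1,
                                   atol=1e-9)

    def test_overlapping_groups_rejected(self):
        top, frame = _random_system(10, seed=11)
        with pytest.raises(ValueError, match="overlap"):
            pair_energies(frame, Selection("l", [0, 1]),
                          Selection("s", [1, 2]), top)

    def test_bound_ligand_more_attractive_than_displaced(self, two_pose,
                                                         two_pose_selections):
        """Shape complementarity: vdW of the bound pose is negative and
        stronger than after pulling the ligand out of the pocket."""
        _, top, stream, _ = two_pose
        frame = next(iter(stream))
        lig = two_pose_selections["ligand"]
        env = Selection("env", np.setdiff1d(np.arange(top.n_atoms),
                                            lig.indices))
        _, v_bound = pair_energies(frame, lig, env, top)
        u = frame.coordinates[lig.indices].mean(0) \
            - frame.coordinates[env.indices].mean(0)
        u /= np.linalg.norm(u)
        coords = frame.coordinates.copy()
        coords[lig.indices] += 2.0 * u  # well outside the contact shell
        _, v_out = pair_energies(Frame(coords), lig, env, top)
        assert v_bound < 0
        assert v_bound < v_out


class TestBlockAverage:
    def test_constant_series_zero_error(self):
        est = block_average(np.full(64, 3.2))
        assert est.mean == pytest.approx(3.2)
        assert est.error == pytest.approx(0.0, abs=1e-14)

    def test_iid_error_matches_sqrt_n(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 2.0, size=10_000)
        est = block_average(x)
        assert est.error == pytest.approx(2.0 / math.sqrt(10_000), rel=0.10)
        # small block sizes agree for uncorrelated data (large blocks are
        # noisy: few blocks per estimate)
        errs = [e for _, e in est.block_curve[:6]]
        assert max(errs) / min(errs) < 1.2

    def test_ar1_plateau_recovers_statistical_inefficiency(self):
        phi, sigma, n = 0.9, 1.0, 100_000
        x = gen_ar1_series(phi, sigma, n, seed=13)
        est = block_average(x)
        sigma_x = sigma / math.sqrt(1 - phi ** 2)
        expected = sigma_x / math.sqrt(n) * math.sqrt((1 + phi) / (1 - phi))
        assert est.error == pytest.approx(expected, rel=0.15)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            block_average(np.array([1.0, 2.0, 3.0]))

    def test_block_curve_present(self):
        est = block_average(np.random.default_rng(14).normal(size=64))
        sizes = [s for s, _ in est.block_curve]
        assert sizes == [1, 2, 4, 8, 16]


class TestCombineRuns:
    def test_single_run_unchanged(self):
        est = EnergyEstimate(mean=-250.0, error=3.0, n_samples=100)
        out = combine_runs([est])
        assert out.mean == est.mean and out.error == est.error

    def test_error_propagation_formula(self):
        out = combine_runs([EnergyEstimate(0.0, 3.0, 10),
                            EnergyEstimate(2.0, 4.0, 10)])
        assert out.mean == pytest.approx(1.0)
        assert out.error == pytest.approx(math.sqrt(9 + 16) / 2)

    def test_identical_runs_shrink_error_by_sqrt_k(self):
        runs = [EnergyEstimate(-50.0, 2.0, 10)] * 4
        out = combine_runs(runs)
        assert out.mean == pytest.approx(-50.0)
        assert out.error == pytest.approx(2.0 / 2.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            combine_runs([])
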