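"""Schlitter entropy: covariance accumulation, closed forms, invariances."""

import numpy as np
import pytest

from glycotraj.entropy import (CovarianceAccumulator, accumulate,
                               entropy_convergence, quantum_harmonic_entropy,
                               schlitter_entropy, schlitter_entropy_1d)
from glycotraj.model_io import Frame, FrameStream, Selection
from glycotraj.synthetic import (GaussianTrajSpec, gen_gaussian_trajectory,
                                 sample_harmonic_positions)


class TestCovarianceAccumulator:
    def test_identical_frames_give_zero_covariance(self):
        acc = CovarianceAccumulator(n_dof=6)
        x = np.arange(6.0)
        acc.add(x)
        acc.add(x)
        np.testing.assert_allclose(acc.finalize(), 0, atol=1e-14)

    def test_streaming_equals_batch(self):
        rng = np.random.default_rng(0)
        xs = rng.normal(0, 0.1, size=(500, 9))
        acc = CovarianceAccumulator(n_dof=9)
        for x in xs:
            acc.add(x)
        batch = np.cov(xs.T, bias=True)
        np.testing.assert_allclose(acc.finalize(), batch, atol=1e-10)

    def test_batch_interface_matches_per_frame(self):
        rng = np.random.default_rng(1)
        xs = rng.normal(0, 0.1, size=(200, 6))
        a1 = CovarianceAccumulator(n_dof=6)
        a2 = CovarianceAccumulator(n_dof=6)
        for x in xs:
            a1.add(x)
        a2.add_batch(xs)
        np.testing.assert_allclose(a1.finalize(), a2.finalize(), atol=1e-12)

    def test_diagonal_recovery_large_sample(self):
        rng = np.random.default_rng(2)
        xs = rng.normal(0, 0.1, size=(100_000, 6))
        acc = CovarianceAccumulator(n_dof=6)
        acc.add_batch(xs)
        np.testing.assert_allclose(np.diag(acc.finalize()), 0.01, rtol=0.02)

    def test_finalized_matrix_is_symmetric_psd(self):
        rng = np.random.default_rng(3)
        acc = CovarianceAccumulator(n_dof=12)
        acc.add_batch(rng.normal(size=(50, 12)))
        cov = acc.finalize()
        np.testing.assert_allclose(cov, cov.T, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_subset_fit_requires_selection(self):
        with pytest.raises(ValueError, match="fit_selection"):
            CovarianceAccumulator(n_dof=3, fit_mode="subset")

    def test_fit_requires_reference(self):
        acc = CovarianceAccumulator(n_dof=9, fit_mode="self")
        frame = Frame(np.random.default_rng(4).normal(size=(3, 3)))
        with pytest.raises(ValueError, match="reference"):
            accumulate(acc, frame, Selection("all", np.arange(3)))


class TestSchlitterEntropy:
    def test_zero_covariance_gives_zero(self):
        res = schlitter_entropy(np.zeros((9, 9)), [12.0] * 3, 300.0)
        assert res.s == 0.0

    def test_matrix_path_matches_scalar_closed_form(self):
        """Isotropic one-atom covariance equals 3x the 1-dof closed form."""
        var = 0.0025
        res = schlitter_entropy(np.eye(3) * var, [12.0], 300.0)
        assert res.s == pytest.approx(3 * schlitter_entropy_1d(var, 12.0, 300.0),
                                      rel=1e-12)

    def test_rotation_invariance_per_atom_blocks(self):
        from scipy.spatial.transform import Rotation
        rng = np.random.default_rng(5)
        a = rng.normal(size=(3, 3))
        cov_atom = a @ a.T * 1e-4
        cov = np.zeros((6, 6))
        cov[:3, :3] = cov_atom
        cov[3:, 3:] = cov_atom * 2
        masses = [12.0, 12.0]
        s0 = schlitter_entropy(cov, masses).s
        r = Rotation.random(random_state=6).as_matrix()
        rot = np.zeros((6, 6))
        rot[:3, :3] = r
        rot[3:, 3:] = r
        s1 = schlitter_entropy(rot @ cov @ rot.T, masses).s
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_zero_fluctuation_atoms_do_not_contribute(self):
        cov = np.zeros((6, 6))
        cov[:3, :3] = np.eye(3) * 0.001
        s_with = schlitter_entropy(cov, [12.0, 40.0]).s
        s_alone = schlitter_entropy(np.eye(3) * 0.001, [12.0]).s
        assert s_with == pytest.approx(s_alone, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(6, 6))
        cov = a @ a.T * 1e-4
        masses = np.array([12.0, 16.0])
        perm = np.array([3, 4, 5, 0, 1, 2])
        s0 = schlitter_entropy(cov, masses).s
        s1 = schlitter_entropy(cov[np.ix_(perm, perm)], masses[::-1]).s
        assert s1 == pytest.approx(s0, rel=1e-10)

    def test_non_psd_covariance_reports_eigenvalue(self):
        cov = -np.eye(3) * 1e-3
        with pytest.raises(ValueError, match="eigenvalue"):
            schlitter_entropy(cov, [12.0])


class TestGaussianOracle:
    def test_estimate_matches_closed_form(self):
        spec = GaussianTrajSpec(n_atoms=3, masses=np.full(3, 12.011),
                                covariance=np.full(9, 0.0025),
                                n_frames=50_000, seed=42)
        top, stream, closed = gen_gaussian_trajectory(spec)
        acc = CovarianceAccumulator(n_dof=9)
        acc.add_batch(stream.coordinates().reshape(-1, 9))
        est = schlitter_entropy(acc.finalize(), top.masses()).s
        assert est == pytest.approx(closed, rel=0.02)

    def test_full_covariance_spec(self):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(6, 6))
        cov = a @ a.T * 1e-4
        spec = GaussianTrajSpec(n_atoms=2, masses=[12.0, 16.0],
                                covariance=cov, n_frames=30_000, seed=9)
        top, stream, closed = gen_gaussian_trajectory(spec)
        acc = CovarianceAccumulator(n_dof=6)
        acc.add_batch(stream.coordinates().reshape(-1, 6))
        est = schlitter_entropy(acc.finalize(), top.masses()).s
        assert est == pytest.approx(closed, rel=0.03)


class TestQuantumBound:
    @pytest.mark.parametrize("xi", [0.1, 1.0, 5.0])
    def test_schlitter_bounds_exact_oscillator_entropy(self, xi):
        x = sample_harmonic_positions(xi, 12.0, 300.0, 50_000, seed=11)
        s_schl = schlitter_entropy_1d(float(x.var()), 12.0, 300.0)
        assert s_schl >= quantum_harmonic_entropy(xi)

    def test_classical_limit_is_tight(self):
        x = sample_harmonic_positions(0.1, 12.0, 300.0, 100_000, seed=12)
        s_schl = schlitter_entropy_1d(float(x.var()), 12.0, 300.0)
        s_exact = quantum_harmonic_entropy(0.1)
        assert (s_schl - s_exact) / s_exact <= 0.05


class TestConvergence:
    def test_single_frame_checkpoint_gives_zero(self):
        rng = np.random.default_rng(13)
        stream = FrameStream.from_array(rng.normal(0, 0.05, (10, 3, 3)))
        res = entropy_convergence(stream, Selection("all", np.arange(3)),
                                  [12.0] * 3, 300.0, [1, 10])
        assert res[0].s == 0.0
        assert res[1].s > 0.0

    def test_checkpoint_series_converges_to_closed_form(self):
        spec = GaussianTrajSpec(n_atoms=2, masses=[12.0, 12.0],
                                covariance=np.full(6, 0.004),
                                n_frames=40_000, seed=14)
        top, stream, closed = gen_gaussian_trajectory(spec)
        res = entropy_convergence(stream, Selection("all", np.arange(2)),
                                  top.masses(), 300.0, [1000, 40_000])
        assert res[-1].s == pytest.approx(closed, rel=0.02)
        assert res[0].s <= res[-1].s * 1.02

    def test_seeded_replicas_report_spread(self):
        finals = []
        for seed in (21, 22):
            spec = GaussianTrajSpec(n_atoms=2, masses=[12.0, 12.0],
                                    covariance=np.full(6, 0.004),
                                    n_frames=5000, seed=seed)
            top, stream, _ = gen_gaussian_trajectory(spec)
            res = entropy_convergence(stream, Selection("all", np.arange(2)),
                                      top.masses(), 300.0, [5000])
            finals.append(res[-1].s)
        sd = np.std(finals, ddof=1)
        assert 0 <= sd < 0.05 * np.mean(finals)

    def test_checkpoint_beyond_stream_warns(self):
        rng = np.random.default_rng(15)
        stream = FrameStream.from_array(rng.normal(0, 0.05, (10, 2, 3)))
        with pytest.warns(UserWarning, match="ended"):
            res = entropy_convergence(stream, Selection("all", np.arange(2)),
                                      [12.0, 12.0], 300.0, [5, 100])
        assert len(res) == 2

    def test_fit_mode_ordering_on_two_pose_ligand(self, two_pose,
                                                  two_pose_selections):
        """Fitting on the protein keeps the ligand's rototranslational
        freedom in the covariance, so S(protein fit) >= S(self fit)."""
        _, top, stream, _ = two_pose
        lig = two_pose_selections["ligand"]
        masses = top.masses()[lig.indices]
        ref = next(iter(stream))
        s_protein = entropy_convergence(
            stream, lig, masses, 300.0, [2000], fit_mode="subset",
            fit_selection=two_pose_selections["backbone"], reference=ref)[0].s
        s_self = entropy_convergence(
            stream, lig, masses, 300.0, [2000], fit_mode="self",
            reference=ref)[0].s
        assert s_protein >= s_self
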