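"""Essential dynamics, elastic-network modes, KLD convergence and hinge AUD."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp

import mdscope as m
from mdscope import synthetic as syn
from mdscope.modes import (
    ENM_N_MODES,
    kld_time_course,
    mode_conformers,
    wrap_angle_deg,
)

from .oracles import covariance_brute, gaussian_kld_closed_form, triangle_enm_eigenvalues


class TestCovariance:
    def test_static_trajectory_gives_zero_matrix(self):
        st = syn.ca_chain_structure(4)
        traj = m.Trajectory(np.repeat(st.coords[None], 6, axis=0), 10.0, st)
        cov = m.covariance_matrix(traj, m.select_atoms(st, "all"), offset=1)
        assert np.abs(cov).max() < 1e-20

    def test_matches_brute_force_double_loop(self, rng):
        st = syn.ca_chain_structure(2)
        coords = st.coords[None] + rng.normal(0, 1, (4, 2, 3))
        traj = m.Trajectory(coords, 10.0, st)
        cov = m.covariance_matrix(traj, m.select_atoms(st, "all"), offset=1)
        np.testing.assert_allclose(cov, covariance_brute(coords), atol=1e-12)

    def test_offset_subsamples_frames(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        c10 = m.covariance_matrix(traj, sel, offset=10)
        manual = m.covariance_matrix(
            traj.with_coords(traj.coords[::10]), sel, offset=1
        )
        np.testing.assert_allclose(c10, manual, atol=1e-12)

    def test_too_few_sampled_frames_rejected(self):
        st = syn.ca_chain_structure(3)
        traj = m.Trajectory(np.repeat(st.coords[None], 5, axis=0), 10.0, st)
        with pytest.raises(ValueError):
            m.covariance_matrix(traj, m.select_atoms(st, "all"), offset=5)

    def test_sample_covariance_converges_to_planted(self):
        r = syn.gen_gaussian_traj(n_residues=10, n_frames=50000, seed=21)
        sel = m.select_atoms(r.structure, "all")
        cov = m.covariance_matrix(r.trajectory, sel, offset=1)
        truth = (
            r.modes.eigenvectors.T
            @ np.diag(r.modes.eigenvalues - r.meta["noise"] ** 2)
            @ r.modes.eigenvectors
            + r.meta["noise"] ** 2 * np.eye(10 * 3)
        )
        rel = np.linalg.norm(cov - truth) / np.linalg.norm(truth)
        assert rel < 0.05


class TestEigendecompose:
    def test_diagonal_matrix_recovers_axes_and_fractions(self):
        cov = np.diag([4.0, 1.0, 0.0, 0.0])
        ms = m.eigendecompose(cov)
        np.testing.assert_allclose(ms.eigenvalues, [4, 1, 0, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(ms.eigenvectors[0]), [1, 0, 0, 0], atol=1e-12)
        np.testing.assert_allclose(ms.eigenvalue_fractions(), [0.8, 0.2, 0, 0], atol=1e-12)

    def test_planted_rank3_directions_recovered(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((30, 3)))
        cov = q @ np.diag([9.0, 4.0, 1.0]) @ q.T
        ms = m.eigendecompose(cov, n_modes=3)
        for k in range(3):
            assert abs(ms.eigenvectors[k] @ q[:, k]) > 0.99

    def test_fractions_sum_to_one(self, rng):
        a = rng.normal(0, 1, (8, 8))
        ms = m.eigendecompose(a @ a.T)
        assert ms.eigenvalue_fractions().sum() == pytest.approx(1.0)
        assert ms.cumulative_fractions()[-1] == pytest.approx(1.0)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            m.eigendecompose(bad)

    def test_eigenvectors_orthonormal(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        ms = m.pca_modes(traj, sel, n_modes=10, offset=1)
        gram = ms.eigenvectors @ ms.eigenvectors.T
        np.testing.assert_allclose(gram, np.eye(10), atol=1e-8)


class TestElasticNetwork:
    def test_triangle_spectrum_matches_symbolic_oracle(self):
        tri = syn.ca_chain_structure(3).with_coords(
            np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        )
        ms = m.enm_modes(tri, m.select_atoms(tri, "all"), cutoff=2.0, n_modes=3)
        np.testing.assert_allclose(ms.eigenvalues, triangle_enm_eigenvalues(), atol=1e-8)
        assert ms.removed_rigid_modes == 6

    def test_exactly_six_rigid_modes_on_valid_structures(self):
        for n in (20, 57):
            chain = syn.ca_chain_structure(n)
            ms = m.enm_modes(chain, m.select_atoms(chain, "name CA"))
            assert ms.removed_rigid_modes == 6
            assert ms.n_modes == min(ENM_N_MODES, 3 * n - 6)
            assert (np.diff(ms.eigenvalues) >= -1e-12).all()  # ascending

    def test_disconnected_graph_rejected_with_component_sizes(self):
        st = syn.ca_chain_structure(8)
        coords = st.coords.copy()
        coords[4:] += 300.0
        with pytest.raises(ValueError, match="disconnected.*components"):
            m.enm_modes(st.with_coords(coords), m.select_atoms(st, "all"))

    def test_hessian_positive_semidefinite(self):
        from mdscope.modes import enm_hessian

        chain = syn.ca_chain_structure(15)
        h = enm_hessian(chain.coords, cutoff=12.0, gamma=1.0)
        w = np.linalg.eigvalsh(h)
        assert w.min() > -1e-10

    def test_elbow_structure_lowest_mode_counter_moves_the_arms(self, hinge):
        st = hinge.structure
        ms = m.enm_modes(st, m.select_atoms(st, "all"), cutoff=12.0, n_modes=5)
        pivot = hinge.meta["pivot_residue"]
        arm_a = st.residue_id < pivot
        arm_b = st.residue_id > pivot
        v = ms.eigenvectors[0].reshape(st.n_atoms, 3)
        cov = np.einsum("ia,ja->ij", v, v)
        c = cov / np.sqrt(np.outer(np.diag(cov), np.diag(cov)))
        assert c[np.ix_(arm_a, arm_b)].mean() < 0
        assert c[np.ix_(arm_a, arm_a)].mean() > 0


class TestProjections:
    def test_mean_frame_projects_to_zero(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        ms = m.pca_modes(traj, sel, n_modes=3, offset=1)
        frame = m.Trajectory(ms.mean_coords.reshape(1, -1, 3), 10.0, traj.atoms)
        proj = m.project_trajectory(frame, ms, k=3)
        np.testing.assert_allclose(proj.values, 0.0, atol=1e-9)

    def test_displacement_along_one_mode_is_orthogonal_to_others(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        ms = m.pca_modes(traj, sel, n_modes=3, offset=1)
        a = 2.5
        frame = (ms.mean_coords + a * ms.eigenvectors[0]).reshape(1, -1, 3)
        proj = m.project_trajectory(m.Trajectory(frame, 10.0, traj.atoms), ms, k=3)
        np.testing.assert_allclose(proj.values[0], [a, 0, 0], atol=1e-9)

    def test_projection_variance_equals_eigenvalue(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        ms = m.pca_modes(traj, sel, n_modes=3, offset=1)
        proj = m.project_trajectory(traj, ms, k=3, selection=sel)
        np.testing.assert_allclose(
            proj.values.var(axis=0), ms.eigenvalues[:3], rtol=1e-8
        )

    def test_dimension_mismatch_rejected(self, gaussian_small):
        traj = gaussian_small.trajectory
        ms = m.pca_modes(traj, m.select_atoms(traj.atoms, "name CA"), n_modes=2, offset=1)
        small = syn.gen_gaussian_traj(n_residues=5, n_frames=3, seed=0).trajectory
        with pytest.raises(ValueError):
            m.project_trajectory(small, ms)


class TestKld:
    def test_identical_series_have_zero_divergence(self, rng):
        x = rng.normal(0, 1, 5000)
        assert m.kld_histogram(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_shifted_gaussians_match_closed_form(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 100000)
        b = rng.normal(1, 1, 100000)
        expected = gaussian_kld_closed_form(0, 1, 1, 1)  # = 0.5
        assert m.kld_histogram(a, b, n_bins=100) == pytest.approx(expected, rel=0.10)

    def test_halves_divergence_shrinks_with_sample_size(self):
        means = []
        for n in (1000, 10000, 100000):
            vals = []
            for seed in range(5):
                x = np.random.default_rng(seed).normal(0, 1, n)
                vals.append(m.kld_histogram(x[: n // 2], x[n // 2:]))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_divergence_never_negative(self, rng):
        for _ in range(20):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 300)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 300)
            assert m.kld_histogram(a, b) >= 0.0

    def test_too_few_bins_rejected(self, rng):
        x = rng.normal(0, 1, 100)
        with pytest.raises(ValueError):
            m.kld_histogram(x, x, n_bins=1)

    def test_time_course_runs_on_projection_series(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        ms = m.pca_modes(traj, sel, n_modes=2, offset=1)
        proj = m.project_trajectory(traj, ms, k=2, selection=sel)
        df = kld_time_course(proj, n_points=5)
        assert {"time_ns", "pc1", "pc2"} <= set(df.columns)
        assert (df[["pc1", "pc2"]].to_numpy() >= 0).all()


class TestModeFluctuations:
    def test_single_concentrated_mode_localizes_fluctuation(self):
        v = np.zeros(9)
        v[3] = 1.0  # all weight on atom 1, x component
        ms = m.ModeSet(
            eigenvectors=v[None], eigenvalues=np.array([2.0]),
            mean_coords=np.zeros(9), source="PCA",
        )
        prof = m.mode_fluctuations(ms)
        np.testing.assert_allclose(prof["msf"], [0.0, 2.0, 0.0], atol=1e-12)

    def test_all_pca_modes_reproduce_trajectory_rmsf(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        full = m.pca_modes(traj, sel, n_modes=3 * len(sel), offset=1)
        prof_modes = m.mode_fluctuations(full)
        prof_traj = m.rmsf(traj, sel)
        np.testing.assert_allclose(
            prof_modes["msf"].to_numpy(),
            prof_traj["rmsf"].to_numpy() ** 2,
            rtol=1e-6,
        )

    def test_elbow_enm_peripheries_fluctuate_more_than_the_hinge(self, hinge):
        st = hinge.structure
        ms = m.enm_modes(st, m.select_atoms(st, "all"), cutoff=12.0, n_modes=5)
        prof = m.mode_fluctuations(ms, first_k=3)
        by_res = prof.groupby("residue_id")["bfactor"].mean()
        pivot = hinge.meta["pivot_residue"]
        assert by_res.iloc[0] > by_res.loc[pivot]
        assert by_res.iloc[-1] > by_res.loc[pivot]


class TestModeConformers:
    def test_projection_recovers_the_generating_sine(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        ms = m.pca_modes(traj, sel, n_modes=3, offset=1)
        conf = mode_conformers(ms, mode_index=1, amplitude=3.0, n_frames=24)
        proj = m.project_trajectory(conf, ms, k=3)
        t = np.arange(24)
        np.testing.assert_allclose(
            proj.values[:, 1], 3.0 * np.sin(2 * np.pi * t / 24), atol=1e-10
        )
        np.testing.assert_allclose(proj.values[:, [0, 2]], 0.0, atol=1e-10)

    def test_zero_amplitude_collapses_to_the_mean(self, gaussian_small):
        traj = gaussian_small.trajectory
        sel = m.select_atoms(traj.atoms, "name CA")
        ms = m.pca_modes(traj, sel, n_modes=2, offset=1)
        conf = mode_conformers(ms, 0, amplitude=1e-12, n_frames=5)
        np.testing.assert_allclose(
            conf.coords,
            np.repeat(ms.mean_coords.reshape(1, -1, 3), 5, axis=0),
            atol=1e-10,
        )


class TestDihedralAud:
    def test_identical_conformers_give_zero_aud(self, hinge):
        st = hinge.structure
        traj = m.Trajectory(np.repeat(st.coords[None], 4, axis=0), 10.0, st)
        aud = m.dihedral_aud(traj, st)
        ok = ~aud["flagged"]
        assert np.nanmax(aud.loc[ok, ["aud_phi", "aud_psi"]].to_numpy()) < 1e-8

    def test_rigid_body_motion_leaves_dihedrals_unchanged(self, hinge, rng):
        st = hinge.structure
        frames = []
        for _ in range(4):
            q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] = -q[:, 0]
            frames.append(st.coords @ q.T + rng.normal(0, 10, 3))
        traj = m.Trajectory(np.array(frames), 10.0, st)
        aud = m.dihedral_aud(traj, st)
        ok = ~aud["flagged"]
        # dihedral kernels run in float32 internally: ~1e-3 degree precision
        assert np.nanmax(aud.loc[ok, ["aud_phi", "aud_psi"]].to_numpy()) < 1e-2

    def test_planted_phi_rotation_matches_closed_form(self):
        res = syn.gen_two_domain_hinge(theta0_deg=20.0, n_frames=2000, noise=0.0, seed=3)
        mean = res.structure.with_coords(res.trajectory.coords.mean(axis=0))
        aud = m.dihedral_aud(res.trajectory, mean)
        pivot = res.meta["pivot_residue"]
        row = aud[aud.residue_id == pivot].iloc[0]
        assert row["aud_phi"] == pytest.approx(2 * 20.0 / np.pi, rel=0.02)
        others = aud[(aud.residue_id != pivot) & ~aud.flagged]
        assert np.nanmax(others[["aud_phi", "aud_psi"]].to_numpy()) < 1.0
        assert bool(row["hinge_candidate"])

    def test_chain_ends_flagged_not_zeroed(self, hinge):
        st = hinge.structure
        traj = m.Trajectory(st.coords[None], 10.0, st)
        aud = m.dihedral_aud(traj, st)
        assert np.isnan(aud["aud_phi"].iloc[0])  # no preceding C for the first residue
        assert np.isnan(aud["aud_psi"].iloc[-1])


@given(delta=st_hyp.floats(-720, 720, allow_nan=False))
@settings(max_examples=200, deadline=None, derandomize=True, database=None)
def test_wrapped_angle_stays_in_half_open_interval(delta):
    w = wrap_angle_deg(delta)
    assert -180.0 < w <= 180.0 or np.isclose(abs(w), 180.0)


def test_wrapping_treats_179_vs_minus_179_as_two_degrees():
    assert abs(wrap_angle_deg(np.array([-179.0 - 179.0]))[0]) == pytest.approx(2.0)
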