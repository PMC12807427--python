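"""Cartesian PCA: covariance construction, spectra, projections, extremes."""

import numpy as np
import pytest

from ythdyn import pca, structure
from ythdyn.pca import (
    build_covariance,
    contribution_fraction,
    eigendecompose,
    extreme_conformations,
    mode_arrows,
    project,
    sorted_eigh,
)
from ythdyn.structure import Selection, Trajectory, select


@pytest.fixture(scope="module")
def ca_selection(template):
    return select(template, "name CA and protein")


class TestCovariance:
    def test_identical_frames_give_zero_matrix(self, template, ca_selection):
        traj = Trajectory(np.repeat(template.coords[None], 3, axis=0), template)
        cov = build_covariance(traj, ca_selection, template)
        assert np.abs(cov.matrix).max() < 1e-12

    def test_two_frame_closed_form_eigenvalue(self):
        """Two frames differing by a fit-neutral +-delta displacement (zero
        net translation and torque, so the rigid fit is exactly identity):
        a single nonzero eigenvalue |delta|^2 under the population
        convention."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(8, 3)) * 3.0
        base[0] = [1.0, 0.0, 0.0]
        base[1] = [-1.0, 0.0, 0.0]
        base -= base.mean(axis=0)
        s = structure.Structure(
            names=["CA"] * 8, elements=["C"] * 8, residue_indices=range(8),
            residue_names=["GLY"] * 8, chain_ids=["A"] * 8, coords=base)
        d = 0.7
        delta = np.zeros((8, 3))
        # symmetric stretch along the line through atoms 0 and 1
        axis = base[0] - base[1]
        axis /= np.linalg.norm(axis)
        delta[0] = d * axis
        delta[1] = -d * axis
        sel = select(s, "name CA")
        cov = build_covariance(
            Trajectory(np.stack([base + delta, base - delta]), s), sel, s,
            fit_mode="reference")
        vals = np.linalg.eigvalsh(cov.matrix)
        assert vals[-1] == pytest.approx(vals.sum(), abs=1e-10)
        assert vals[-1] == pytest.approx(2 * d * d, abs=1e-10)

    def test_trace_equals_mean_squared_fluctuation(self, template, ca_selection,
                                                   two_state_run):
        trajs, _ = two_state_run
        cov = build_covariance(trajs, ca_selection, template)
        X = pca._fitted_selected_coords(trajs, ca_selection, template)
        msf = ((X - X.mean(axis=0)) ** 2).mean(axis=0).sum()
        assert np.trace(cov.matrix) == pytest.approx(msf, rel=1e-10)


class TestEigendecompose:
    def test_diagonal_matrix(self, ca_selection):
        cov = pca.CovarianceModel(
            mean=np.zeros(3), matrix=np.diag([3.0, 1.0, 0.0]),
            selection=Selection(np.array([0])), n_frames=10)
        res = eigendecompose(cov)
        np.testing.assert_allclose(res.eigenvalues, [3.0, 1.0, 0.0])
        np.testing.assert_allclose(np.abs(res.eigenvectors),
                                   np.eye(3)[:, [0, 1, 2]], atol=1e-12)

    def test_reconstruction_roundtrip(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(12, 12))
        sigma = A @ A.T / 12.0
        vals, vecs = sorted_eigh(sigma)
        np.testing.assert_allclose(vecs @ np.diag(vals) @ vecs.T, sigma,
                                   atol=1e-8)
        assert np.all(np.diff(vals) <= 1e-12)
        np.testing.assert_allclose(vecs.T @ vecs, np.eye(12), atol=1e-8)

    def test_gaussian_recovery_monte_carlo(self):
        """Top eigenvalue of sampled Gaussian data within 10% of the truth."""
        rng = np.random.default_rng(42)
        true_vals = np.array([9.0, 4.0, 1.0, 0.25])
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        cov_true = Q @ np.diag(true_vals) @ Q.T
        X = rng.multivariate_normal(np.zeros(4), cov_true, size=3000)
        emp = (X - X.mean(0)).T @ (X - X.mean(0)) / len(X)
        vals, _ = sorted_eigh(emp)
        assert vals[0] == pytest.approx(9.0, rel=0.1)

    def test_sign_convention_largest_component_positive(self):
        sigma = np.array([[2.0, -1.0], [-1.0, 2.0]])
        _, vecs = sorted_eigh(sigma)
        for j in range(2):
            assert vecs[np.argmax(np.abs(vecs[:, j])), j] > 0

    def test_eigenvalue_sum_equals_trace(self, template, ca_selection,
                                         two_state_run):
        trajs, _ = two_state_run
        cov = build_covariance(trajs, ca_selection, template)
        res = eigendecompose(cov)
        assert res.eigenvalues.sum() == pytest.approx(np.trace(cov.matrix),
                                                      rel=1e-8)

    def test_rigid_fit_leaves_six_null_modes(self, template, ca_selection,
                                             two_state_run):
        trajs, _ = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        null = (res.eigenvalues < 1e-6 * res.eigenvalues[0]).sum()
        assert null >= 6


class TestContributionFraction:
    def test_values_and_normalisation(self):
        res = pca.PCAResult(np.array([3.0, 1.0, 0.0, 0.0]), np.eye(4),
                            np.zeros(4), Selection(np.array([0])))
        assert contribution_fraction(res, 0) == pytest.approx(0.75)
        total = sum(contribution_fraction(res, m) for m in range(4))
        assert total == pytest.approx(1.0)

    def test_two_state_pc1_dominates(self, template, ca_selection,
                                     two_state_run):
        trajs, _ = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        f1 = contribution_fraction(res, 0)
        assert all(f1 > contribution_fraction(res, m)
                   for m in range(1, res.n_modes))


class TestProjection:
    def test_mean_projects_to_zero(self, template, ca_selection, two_state_run):
        trajs, _ = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        mean_coords = template.coords.copy()
        mean_coords[ca_selection.indices] = res.mean.reshape(-1, 3)
        traj = Trajectory(mean_coords[None], template)
        proj = project(traj, res, (0, 1, 2))
        np.testing.assert_allclose(proj.values, 0.0, atol=1e-8)

    def test_projection_variance_equals_eigenvalue(self, template,
                                                   ca_selection, two_state_run):
        trajs, _ = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        values = np.concatenate(
            [project(t, res, (0, 1), template).values for t in trajs])
        for col, mode in enumerate((0, 1)):
            var = values[:, col].var()   # population convention
            assert var == pytest.approx(res.eigenvalues[mode], rel=1e-8)

    def test_unit_displacement_along_mode(self, template, ca_selection,
                                          two_state_run):
        trajs, _ = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        coords = template.coords.copy()
        displaced = res.mean + 2.0 * res.eigenvectors[:, 0]
        coords[ca_selection.indices] = displaced.reshape(-1, 3)
        proj = project(Trajectory(coords[None], template), res, (0, 1))
        assert proj.values[0, 0] == pytest.approx(2.0, abs=1e-8)
        assert proj.values[0, 1] == pytest.approx(0.0, abs=1e-8)

    def test_projection_additive_in_stacked_displacements(
            self, template, ca_selection, two_state_run):
        trajs, _ = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        da = 0.5 * res.eigenvectors[:, 0]
        db = 0.25 * res.eigenvectors[:, 1]

        def frame_with(displacement):
            coords = template.coords.copy()
            coords[ca_selection.indices] = (res.mean
                                            + displacement).reshape(-1, 3)
            return Trajectory(coords[None], template)

        pa = project(frame_with(da), res, (0, 1)).values
        pb = project(frame_with(db), res, (0, 1)).values
        pab = project(frame_with(da + db), res, (0, 1)).values
        np.testing.assert_allclose(pab, pa + pb, atol=1e-10)


class TestExtremes:
    def test_argmin_argmax_and_ties(self):
        proj = pca.ProjectionSet(np.array([[-1.0], [0.0], [3.0]]), (0,))
        assert extreme_conformations(proj, 0) == (0, 2)
        flat = pca.ProjectionSet(np.zeros((4, 1)), (0,))
        assert extreme_conformations(flat, 0) == (0, 0)

    def test_extremes_carry_opposite_state_labels(self, template, ca_selection,
                                                  two_state_run):
        trajs, truth = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        values = np.concatenate(
            [project(t, res, (0,), template).values for t in trajs])
        lo, hi = extreme_conformations(
            pca.ProjectionSet(values, (0,)), 0)
        assert truth.labels[lo] != truth.labels[hi]


class TestModeArrows:
    def test_norm_and_zero_scale(self, template, ca_selection, two_state_run):
        trajs, _ = two_state_run
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        field = mode_arrows(res, 0, scale=1.0)
        assert np.sum(field ** 2) == pytest.approx(1.0)
        assert np.abs(mode_arrows(res, 0, scale=0.0)).max() == 0.0

    def test_field_aligns_with_extreme_difference(self, template, ca_selection,
                                                  template_spec):
        """On a noise-free two-state fixture, PC1 equals the open-minus-closed
        displacement direction (cosine similarity > 0.99)."""
        from ythdyn import synthetic

        dyn = synthetic.DynamicsSpec(seed=3, noise_sigma=1e-4, n_frames=50,
                                     n_replicas=1)
        trajs, truth = synthetic.generate_trajectories(
            template, template_spec, dyn, "two_state")
        res = eigendecompose(build_covariance(trajs, ca_selection, template))
        proj = project(trajs[0], res, (0,), template)
        lo, hi = extreme_conformations(proj, 0)

        def fitted(frame):
            mob = trajs[0].frames[frame, ca_selection.indices]
            R, t, _ = structure.superpose(mob,
                                          template.coords[ca_selection.indices])
            return structure.apply_transform(mob, R, t)

        diff = (fitted(hi) - fitted(lo)).ravel()
        field = mode_arrows(res, 0).ravel()
        cos = np.abs(diff @ field) / np.linalg.norm(diff)
        assert cos > 0.99
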