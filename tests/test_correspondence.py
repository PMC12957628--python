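"""GPA, non-rigid CPD and quasi-landmark matching."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes
from scipy.spatial.transform import Rotation

from craniomorph.correspondence import (CPDParams, QuasiLandmarkMatch,
                                        assemble_corresponded, centroid_size,
                                        correspond_study, cpd_nonrigid, gpa,
                                        kabsch_rotation,
                                        match_quasi_landmarks)
from craniomorph.exceptions import (DegenerateInputError, ParameterError,
                                    RegistrationError)
from craniomorph.mesh_core import LandmarkSet, Specimen, TriangleMesh
from craniomorph.synthetic_data import generate_study, PopulationSpec


def rigid_copy(config, seed=0, translation=(5.0, -3.0, 2.0)):
    R = Rotation.random(random_state=seed).as_matrix()
    return config @ R.T + np.asarray(translation)


class TestGPA:
    def test_identical_configurations(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(10, 3))
        fit = gpa(np.stack([A, A, A]))
        assert fit.rmsd < 1e-12
        # all configurations share one proper rotation into the canonical
        # consensus frame
        for R in fit.rotations:
            np.testing.assert_allclose(R, fit.rotations[0], atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)
        np.testing.assert_allclose(fit.aligned[0], fit.aligned[2],
                                   atol=1e-12)

    def test_rigidly_moved_copy_coincides(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(12, 3))
        fit = gpa(np.stack([A, rigid_copy(A, seed=3)]))
        assert np.abs(fit.aligned[0] - fit.aligned[1]).max() < 1e-8

    def test_relative_rotation_matches_svd_procrustes_oracle(self):
        rng = np.random.default_rng(2)
        A = rng.normal(size=(4, 3))
        B = rigid_copy(A, seed=5)
        Ac, Bc = A - A.mean(0), B - B.mean(0)
        R_oracle, _ = orthogonal_procrustes(Bc, Ac)
        if np.linalg.det(R_oracle) < 0:  # enforce a proper rotation
            U, s, Vt = np.linalg.svd(Bc.T @ Ac)
            R_oracle = U @ np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))]) @ Vt
        np.testing.assert_allclose(kabsch_rotation(Bc, Ac), R_oracle,
                                   atol=1e-10)

    def test_consensus_is_fixed_point(self):
        rng = np.random.default_rng(3)
        configs = rng.normal(size=(5, 8, 3))
        for with_scaling in (False, True):
            fit = gpa(configs, with_scaling=with_scaling)
            refit = gpa(fit.aligned, with_scaling=with_scaling)
            assert np.abs(refit.consensus - fit.consensus).max() < 1e-8

    def test_shape_space_normalises_consensus_size(self):
        rng = np.random.default_rng(4)
        configs = rng.normal(size=(4, 6, 3)) * 7.0
        fit = gpa(configs, with_scaling=True)
        assert centroid_size(fit.consensus) == pytest.approx(1.0, abs=1e-8)
        form = gpa(configs, with_scaling=False)
        for i in range(4):
            assert centroid_size(form.aligned[i]) == pytest.approx(
                centroid_size(configs[i]))

    def test_degenerate_configuration_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        good = np.random.default_rng(0).normal(size=(5, 3))
        with pytest.raises(DegenerateInputError):
            gpa(np.stack([line, good]))

    def test_no_reflections(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 3))
        B = A.copy()
        B[:, 0] *= -1  # mirrored configuration
        fit = gpa(np.stack([A, B]))
        assert np.linalg.det(fit.rotations[0]) == pytest.approx(1.0)
        assert np.linalg.det(fit.rotations[1]) == pytest.approx(1.0)


class TestCPD:
    def test_identity_registration(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(120, 3)) * 40
        res = cpd_nonrigid(Y, Y)
        scale = np.sqrt(((Y - Y.mean(0)) ** 2).sum(1).mean())
        rms = np.sqrt(((res.displaced - Y) ** 2).sum(1).mean())
        assert rms < 1e-6 * scale

    def test_known_smooth_warp_recovery(self):
        rng = np.random.default_rng(0)
        Y = rng.uniform(-1, 1, size=(500, 3))
        Y[:, 2] *= 0.2
        noise_sd = 0.02
        warp = 0.15 * np.sin(2 * np.pi * Y[:, 0] / 2.0)[:, None] \
            * np.array([0.0, 0.0, 1.0])
        X = Y + warp + rng.normal(0, noise_sd, size=Y.shape)
        res = cpd_nonrigid(Y, X, CPDParams(w=0.0, max_iter=300))
        err = res.displaced - (Y + warp)
        assert np.sqrt((err ** 2).sum(1).mean()) < 1.5 * noise_sd

    def test_single_iteration_reports_not_converged(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(50, 3))
        X = Y + rng.normal(0, 0.1, size=Y.shape)
        res = cpd_nonrigid(Y, X, CPDParams(max_iter=1))
        assert not res.converged
        assert res.n_iterations == 1

    def test_sigma2_non_increasing(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(200, 3))
        X = Y + 0.1 * np.sin(Y[:, [0]]) + rng.normal(0, 0.03, size=Y.shape)
        res = cpd_nonrigid(Y, X, CPDParams(w=0.0))
        s2 = np.array(res.sigma2_trace[1:])  # after the first E/M step
        assert (np.diff(s2) <= 1e-9 * s2[0]).all()

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            CPDParams(beta=0)
        with pytest.raises(ParameterError):
            CPDParams(w=1.0)
        with pytest.raises(ParameterError):
            cpd_nonrigid(np.zeros((5, 3)), np.zeros((20, 3)))


class TestMatching:
    def test_identity_matching(self):
        rng = np.random.default_rng(0)
        cloud = rng.normal(size=(50, 3))
        match = match_quasi_landmarks(cloud, cloud, cloud)
        assert match.mask.all()
        np.testing.assert_allclose(match.distances, 0)
        np.testing.assert_array_equal(match.coordinates, cloud)

    def test_far_outlier_is_masked(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(40, 3))
        specimen = base + rng.normal(0, 0.01, size=base.shape)
        specimen[7] += 100.0  # unmatched vertex: base vertex 7 now far
        match = match_quasi_landmarks(base, specimen, specimen,
                                      prune_factor=3.0)
        assert not match.mask[7]
        assert match.mask.sum() == 39

    def test_nearest_neighbour_equals_brute_force(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(60, 3))
        spec = rng.normal(size=(80, 3))
        match = match_quasi_landmarks(base, spec, spec, prune_factor=1e9)
        brute_idx = np.argmin(
            ((base[:, None, :] - spec[None, :, :]) ** 2).sum(-1), axis=1)
        np.testing.assert_array_equal(match.coordinates, spec[brute_idx])


class TestAssemble:
    @staticmethod
    def _match(coords, mask):
        return QuasiLandmarkMatch(coordinates=coords,
                                  mask=mask,
                                  distances=np.zeros(len(coords)))

    def test_mask_intersection(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(6, 3))
        m1 = np.array([0, 1, 1, 1, 1, 0], dtype=bool)  # {1,2,3,4}
        m2 = np.array([0, 0, 1, 1, 1, 1], dtype=bool)  # {2,3,4,5}
        base = TriangleMesh(coords, np.array([[0, 1, 2], [3, 4, 5]]))
        sample = assemble_corresponded(
            [self._match(coords, m1), self._match(coords + 0.01, m2)],
            base, ["a", "b"])
        np.testing.assert_array_equal(np.flatnonzero(sample.mask), [2, 3, 4])
        assert sample.k == 3
        assert sample.coordinates.shape == (2, 9)

    def test_identical_specimens_give_identical_rows(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(10, 3))
        base = TriangleMesh(coords, np.array([[0, 1, 2]]))
        mask = np.ones(10, dtype=bool)
        sample = assemble_corresponded(
            [self._match(coords, mask), self._match(coords, mask)],
            base, ["a", "b"])
        np.testing.assert_allclose(sample.coordinates[0],
                                   sample.coordinates[1], atol=1e-12)

    def test_empty_intersection_rejected(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(6, 3))
        base = TriangleMesh(coords, np.array([[0, 1, 2]]))
        m1 = np.array([1, 1, 1, 0, 0, 0], dtype=bool)
        m2 = np.array([0, 0, 0, 1, 1, 1], dtype=bool)
        with pytest.raises(RegistrationError):
            assemble_corresponded(
                [self._match(coords, m1), self._match(coords, m2)],
                base, ["a", "b"])


class TestFullPipeline:
    def test_rigid_equivariance(self):
        """Rigidly moving one specimen's input leaves its quasi-landmark
        row unchanged: the landmark GPA absorbs the motion before CPD."""
        study = generate_study(
            [PopulationSpec(label="A", n_female=2, n_male=1)], seed=7)
        specimens = study.specimens
        sample = correspond_study(specimens, base=0,
                                  cpd_params=CPDParams(max_iter=60))

        moved = []
        R = Rotation.from_euler("xyz", [15, -40, 70], degrees=True).as_matrix()
        for i, s in enumerate(specimens):
            if i == 1:
                mesh = TriangleMesh(s.mesh.vertices @ R.T + 25.0,
                                    s.mesh.faces)
                lmk = LandmarkSet.from_array(
                    s.landmarks.as_array() @ R.T + 25.0)
                moved.append(Specimen(id=s.id, population=s.population,
                                      sex=s.sex, mesh=mesh, landmarks=lmk))
            else:
                moved.append(s)
        sample2 = correspond_study(moved, base=0,
                                   cpd_params=CPDParams(max_iter=60))
        np.testing.assert_array_equal(sample.mask, sample2.mask)
        scale = np.abs(sample.coordinates).max()
        assert np.abs(sample.coordinates - sample2.coordinates).max() \
            < 1e-6 * scale
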