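"""Landmark alignment and best-fit ICP refinement."""

import numpy as np
import pytest
from scipy.optimize import minimize

from condylometry.core import LandmarkSet, REGISTRATION_LANDMARKS
from condylometry.register import (
    RegistrationError,
    RigidTransform,
    compose,
    icp_refine,
    invert,
    landmark_align,
)
from condylometry.synth import apply_rigid, perturb_surface

from .conftest import icosphere


def jitter_landmarks(lms, rng, sigma):
    return LandmarkSet(
        {
            n: lms[n]
            + (rng.normal(0, sigma, 3) if n in REGISTRATION_LANDMARKS else 0.0)
            for n in lms.names()
        }
    )


class TestRigidTransform:
    def test_non_orthonormal_rejected(self):
        with pytest.raises(RegistrationError, match="orthonormal"):
            RigidTransform(np.eye(3) * 2.0, np.zeros(3))

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(RegistrationError, match="det"):
            RigidTransform(R, np.zeros(3))

    def test_compose_invert_identity(self):
        a = RigidTransform.from_axis_angle([1, 2, 3], 40.0, [5, -1, 2])
        i = compose(a, invert(a))
        np.testing.assert_allclose(i.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(i.translation, 0.0, atol=1e-12)

    def test_compose_with_identity(self):
        b = RigidTransform.from_axis_angle([0, 1, 0], 12.0, [1, 1, 1])
        i = RigidTransform.identity()
        out = compose(i, b)
        np.testing.assert_allclose(out.rotation, b.rotation, atol=1e-15)
        np.testing.assert_allclose(out.translation, b.translation, atol=1e-15)

    def test_rotation_angles_add_on_same_axis(self):
        r30 = RigidTransform.from_axis_angle([0, 0, 1], 30.0)
        r60 = RigidTransform.from_axis_angle([0, 0, 1], 60.0)
        r90 = RigidTransform.from_axis_angle([0, 0, 1], 90.0)
        out = compose(r30, r60)
        np.testing.assert_allclose(out.rotation, r90.rotation, atol=1e-12)


class TestLandmarkAlign:
    def test_identity_on_equal_sets(self, phantom):
        _, lms = phantom
        T = landmark_align(lms, lms)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_recovery_of_known_motion(self, phantom, seed):
        _, lms = phantom
        rng = np.random.default_rng(seed)
        T = RigidTransform.from_axis_angle(
            rng.normal(size=3), rng.uniform(-30, 30), rng.uniform(-20, 20, 3)
        )
        moved = apply_rigid(lms, T)
        rec = landmark_align(moved, lms)
        np.testing.assert_allclose(rec.rotation, invert(T).rotation, atol=1e-9)
        np.testing.assert_allclose(
            rec.translation, invert(T).translation, atol=1e-9
        )

    def test_reflection_correspondence_gives_proper_rotation(self):
        # a mirrored chiral configuration is best fit by a reflection;
        # the solver must still return det +1 with nonzero residual
        pts = {
            "mental_foramen_L": [10.0, 5.0, 0.0],
            "mental_foramen_R": [10.0, -5.0, 2.0],
            "lingula_L": [0.0, 4.0, 8.0],
            "lingula_R": [3.0, -4.0, 5.0],
        }
        fixed = LandmarkSet(pts)
        mirrored = LandmarkSet(
            {n: np.asarray(p) * [1.0, 1.0, -1.0] for n, p in pts.items()}
        )
        T = landmark_align(mirrored, fixed)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-12)
        names = fixed.names()
        residual = np.linalg.norm(
            T.apply_points(mirrored.as_array(names)) - fixed.as_array(names)
        )
        assert residual > 0.1

    def test_too_few_shared_landmarks_rejected(self):
        a = LandmarkSet({"Sg_L": [0, 0, 1], "Li_L": [0, 0, 0]})
        b = LandmarkSet({"Sg_L": [0, 0, 1], "Li_L": [0, 0, 0]})
        with pytest.raises(RegistrationError, match=">=3"):
            landmark_align(a, b)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_minimizer(self, seed):
        """Kabsch equals a direct numerical minimizer of the residual."""
        rng = np.random.default_rng(seed)
        fixed_pts = rng.uniform(-10, 10, size=(4, 3))
        names = list(REGISTRATION_LANDMARKS)
        T = RigidTransform.from_axis_angle(
            rng.normal(size=3), rng.uniform(-20, 20), rng.uniform(-5, 5, 3)
        )
        moving_pts = invert(T).apply_points(fixed_pts) + rng.normal(
            0, 0.2, size=(4, 3)
        )
        fixed = LandmarkSet(dict(zip(names, fixed_pts)))
        moving = LandmarkSet(dict(zip(names, moving_pts)))
        rec = landmark_align(moving, fixed)
        res_kabsch = np.sum(
            (rec.apply_points(moving_pts) - fixed_pts) ** 2
        )

        def objective(x):
            w, t = x[:3], x[3:]
            angle = np.linalg.norm(w)
            Tx = (
                RigidTransform.from_axis_angle(w / angle, np.rad2deg(angle), t)
                if angle > 1e-12
                else RigidTransform(np.eye(3), t)
            )
            return np.sum((Tx.apply_points(moving_pts) - fixed_pts) ** 2)

        best = min(
            minimize(objective, x0, method="Nelder-Mead",
                     options={"xatol": 1e-10, "fatol": 1e-14,
                              "maxiter": 20000}).fun
            for x0 in (np.zeros(6), np.concatenate([rng.normal(0, 0.5, 3),
                                                    rng.normal(0, 2, 3)]))
        )
        assert res_kabsch <= best + 1e-6


class TestICP:
    def test_identical_meshes_converge_immediately(self, phantom):
        mesh, _ = phantom
        res = icp_refine(mesh, mesh)
        assert res.rms < 1e-9
        assert res.iterations == 1
        assert res.converged

    @pytest.mark.parametrize("variant", ["point_to_point", "point_to_plane"])
    def test_jittered_landmark_init_reaches_precision(self, phantom, variant):
        mesh, lms = phantom
        rng = np.random.default_rng(42)
        T = RigidTransform.from_axis_angle(
            rng.normal(size=3), 10.0, [5.0, -2.0, 3.0]
        )
        moved = apply_rigid(mesh, T)
        jlms = jitter_landmarks(apply_rigid(lms, T), rng, 0.5)
        init = landmark_align(jlms, lms)
        res = icp_refine(moved, mesh, init=init, max_samples=4000,
                         variant=variant)
        assert res.rms <= 0.01

    def test_offset_shell_rms_is_irreducible(self):
        sphere = icosphere(10.0, 3)
        shell = perturb_surface(sphere, 0.2, 0.0)
        res = icp_refine(shell, sphere, trim_fraction=0.0)
        assert res.converged
        assert res.rms == pytest.approx(0.2, abs=0.02)

    def test_rms_non_increasing(self, phantom):
        mesh, lms = phantom
        rng = np.random.default_rng(7)
        T = RigidTransform.from_axis_angle([1, 0, 0], 8.0, [2, 2, -1])
        moved = apply_rigid(mesh, T)
        jlms = jitter_landmarks(apply_rigid(lms, T), rng, 0.5)
        res = icp_refine(moved, mesh, init=landmark_align(jlms, lms),
                         max_samples=3000)
        h = res.rms_history
        assert all(b <= a + 1e-12 for a, b in zip(h, h[1:]))

    def test_no_overlap_flagged_not_raised(self, phantom):
        mesh, _ = phantom
        far = RigidTransform(np.eye(3), np.array([500.0, 0.0, 0.0]))
        res = icp_refine(
            apply_rigid(mesh, far), mesh, max_iterations=3
        )
        assert res.overlap_warning

    @pytest.mark.parametrize("seed", range(8))
    def test_recovery_of_random_motions(self, phantom, seed):
        """Landmark + ICP recovers random motions (rot <= 30 deg,
        trans <= 20 mm) to within 0.01 mm max vertex discrepancy."""
        mesh, lms = phantom
        rng = np.random.default_rng(seed)
        T = RigidTransform.from_axis_angle(
            rng.normal(size=3), rng.uniform(-30, 30), rng.uniform(-20, 20, 3)
        )
        moved = apply_rigid(mesh, T)
        init = landmark_align(apply_rigid(lms, T), lms)
        res = icp_refine(moved, mesh, init=init, max_samples=4000)
        discrepancy = np.abs(
            res.transform.apply_points(moved.vertices) - mesh.vertices
        ).max()
        assert discrepancy <= 0.01
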