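"""Rigid-transform algebra, frame constructions, Euler sequences, Kabsch."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vertekin.geomkin import (
    BeadSet,
    DegenerateGeometryError,
    EulerAngles,
    EulerSequence,
    LandmarkSet,
    RigidTransform,
    anatomic_frame,
    euler_from_rotation,
    fit_rigid,
    frame_from_three_points,
    relative_pose,
    rotation_from_euler,
)

from conftest import rotation_angle_deg


class TestRigidTransform:
    def test_rejects_reflection_and_nonorthonormal(self):
        with pytest.raises(ValueError, match="determinant"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
        with pytest.raises(ValueError, match="orthonormal"):
            RigidTransform(np.eye(3) * 1.5, np.zeros(3))

    def test_compose_inverse_roundtrip(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            A = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3))
            B = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3))
            p = rng.normal(size=(5, 3))
            np.testing.assert_allclose((A @ B).apply(p), A.apply(B.apply(p)), atol=1e-12)
            assert (A @ A.inverse()).is_close(RigidTransform.identity(), atol=1e-12)


class TestFrameFromThreePoints:
    @pytest.mark.parametrize(
        "pts, rot, trans",
        [
            # canonical basis
            ([(0, 0, 0), (1, 0, 0), (0, 1, 0)], np.eye(3), (0, 0, 0)),
            # pure translation
            ([(5, 5, 5), (6, 5, 5), (5, 6, 5)], np.eye(3), (5, 5, 5)),
            # 90 deg about Z: x_hat=(0,1,0), z_hat=(0,0,1)
            (
                [(0, 0, 0), (0, 1, 0), (-1, 0, 0)],
                np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float),
                (0, 0, 0),
            ),
        ],
    )
    def test_examples(self, pts, rot, trans):
        T = frame_from_three_points(*pts)
        np.testing.assert_allclose(T.rotation, rot, atol=1e-12)
        np.testing.assert_allclose(T.translation, trans, atol=1e-12)

    def test_collinear_points_raise_with_points_named(self):
        with pytest.raises(DegenerateGeometryError, match=r"\[2\.0, 0\.0, 0\.0\]"):
            frame_from_three_points((0, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_equivariance_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(3, 3)) * 10
        T = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3))
        F = frame_from_three_points(*pts)
        F2 = frame_from_three_points(*T.apply(pts))
        assert F2.is_close(T @ F, atol=1e-9)


class TestAnatomicFrame:
    def test_axis_aligned_landmarks(self):
        lm = LandmarkSet("cervical", (10, 0, 0), (0, 5, 0), (0, -5, 0))
        T = anatomic_frame(lm)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(T.translation, (10, 0, 0), atol=1e-12)

    def test_translation_equivariance(self):
        d = np.array([0.0, 0.0, 7.0])
        a = anatomic_frame(LandmarkSet("cervical", (10, 0, 0), (0, 5, 0), (0, -5, 0)))
        b = anatomic_frame(
            LandmarkSet("cervical", (10, 0, 7), (0, 5, 7), (0, -5, 7))
        )
        np.testing.assert_allclose(b.rotation, a.rotation, atol=1e-12)
        np.testing.assert_allclose(b.translation, a.translation + d, atol=1e-12)

    def test_gram_schmidt_construction(self):
        # origin off the transverse plane: x is the unit origin direction
        T = anatomic_frame(LandmarkSet("lumbar", (10, 0, 2), (0, 5, 0), (0, -5, 0)))
        x = np.array([10, 0, 2]) / np.linalg.norm([10, 0, 2])
        np.testing.assert_allclose(T.rotation[:, 0], x, atol=1e-12)
        np.testing.assert_allclose(T.rotation[:, 1], (0, 1, 0), atol=1e-12)
        np.testing.assert_allclose(T.rotation[:, 2], np.cross(x, (0, 1, 0)), atol=1e-12)

    def test_always_right_handed(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            pts = rng.normal(size=(3, 3)) * 10
            try:
                T = anatomic_frame(LandmarkSet("cervical", *pts))
            except DegenerateGeometryError:
                continue
            assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_origin_on_lr_axis_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            anatomic_frame(LandmarkSet("cervical", (0, 2, 0), (0, 5, 0), (0, -5, 0)))


class TestRelativePose:
    def test_identities(self):
        T = RigidTransform(Rotation.from_euler("XYZ", [10, 20, 30], degrees=True).as_matrix(), (1, 2, 3))
        assert relative_pose(T, T).is_close(RigidTransform.identity(), atol=1e-12)
        assert relative_pose(RigidTransform.identity(), T).is_close(T)

    def test_rotated_parent(self):
        parent = RigidTransform(Rotation.from_euler("Z", 90, degrees=True).as_matrix(), (0, 0, 0))
        child = RigidTransform(np.eye(3), (1, 0, 0))
        rel = relative_pose(parent, child)
        np.testing.assert_allclose(rel.translation, (0, -1, 0), atol=1e-12)
        np.testing.assert_allclose(
            rel.rotation, Rotation.from_euler("Z", -90, degrees=True).as_matrix(), atol=1e-12
        )

    def test_composition_closure(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            A = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3))
            B = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3))
            assert (A @ relative_pose(A, B)).is_close(B, atol=1e-9)


class TestEuler:
    @pytest.mark.parametrize("seq", [EulerSequence.YXZ, EulerSequence.XZY])
    def test_identity(self, seq):
        e = euler_from_rotation(np.eye(3), seq)
        np.testing.assert_allclose(e.angles, 0, atol=1e-12)
        assert not e.gimbal_lock

    def test_single_axis(self):
        R = Rotation.from_euler("Y", 30, degrees=True).as_matrix()
        e = euler_from_rotation(R, EulerSequence.YXZ)
        np.testing.assert_allclose(e.angles, (30, 0, 0), atol=1e-12)

    def test_composed_sequence(self):
        R = (
            Rotation.from_euler("Y", 20, degrees=True).as_matrix()
            @ Rotation.from_euler("X", 10, degrees=True).as_matrix()
            @ Rotation.from_euler("Z", 5, degrees=True).as_matrix()
        )
        e = euler_from_rotation(R, EulerSequence.YXZ)
        np.testing.assert_allclose(e.angles, (20, 10, 5), atol=1e-9)

    def test_roundtrip_random_rotations(self):
        rng = np.random.default_rng(12345)
        n = 0
        while n < 1000:
            R = Rotation.random(random_state=rng).as_matrix()
            for seq in EulerSequence:
                e = euler_from_rotation(R, seq)
                if e.gimbal_lock or abs(e.angles[1]) > 89.9:
                    continue
                np.testing.assert_allclose(rotation_from_euler(e), R, atol=1e-9)
            n += 1

    def test_gimbal_lock_flagged_with_zero_third_angle(self):
        R = Rotation.from_euler("YXZ", [25, 90, 40], degrees=True).as_matrix()
        e = euler_from_rotation(R, EulerSequence.YXZ)
        assert e.gimbal_lock
        assert e.angles[2] == 0.0
        # the flagged factorisation still reproduces the rotation
        np.testing.assert_allclose(rotation_from_euler(e), R, atol=1e-9)

    def test_angle_wrapping(self):
        e = EulerAngles(EulerSequence.YXZ, (190.0, -181.0, 360.0))
        np.testing.assert_allclose(e.angles, (-170.0, 179.0, 0.0), atol=1e-12)


def _grid_search_rigid(P, Q, span, n=7, levels=6):
    """Brute-force rigid fit: coarse-to-fine grid over the rotation vector,
    translation chosen to match centroids for each candidate rotation."""
    best = (None, np.inf)
    center = np.zeros(3)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    for _ in range(levels):
        axes = [np.linspace(c - span, c + span, n) for c in center]
        for rx in axes[0]:
            for ry in axes[1]:
                for rz in axes[2]:
                    R = Rotation.from_rotvec([rx, ry, rz]).as_matrix()
                    t = cq - R @ cp
                    res = np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=-1)))
                    if res < best[1]:
                        best = ((rx, ry, rz), res)
        center = np.array(best[0])
        span /= n / 2.0
    return best[1]


class TestFitRigid:
    def _beads(self):
        return BeadSet("b", [(0, 0, 0), (10, 0, 0), (0, 10, 0), (4, 4, 6)])

    def test_exact_recovery(self):
        ref = self._beads()
        T_true = RigidTransform(
            Rotation.from_euler("Z", 90, degrees=True).as_matrix(), (1, 2, 3)
        )
        T, rms = fit_rigid(ref, ref.transformed(T_true))
        assert rms == pytest.approx(0.0, abs=1e-9)
        assert T.is_close(T_true, atol=1e-9)

    def test_identity(self):
        ref = self._beads()
        T, rms = fit_rigid(ref, ref)
        assert T.is_close(RigidTransform.identity(), atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_matches_three_point_frame_on_exact_motion(self):
        ref = self._beads()
        rng = np.random.default_rng(2)
        T_true = RigidTransform(Rotation.random(random_state=rng).as_matrix(), rng.normal(size=3))
        obs = ref.transformed(T_true)
        T_ls, _ = fit_rigid(ref, obs)
        f_ref = frame_from_three_points(*ref.centroids[:3])
        f_obs = frame_from_three_points(*obs.centroids[:3])
        T_3pt = f_obs @ f_ref.inverse()
        assert T_ls.is_close(T_3pt, atol=1e-9)

    def test_noisy_fit_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        P = self._beads().centroids
        Q = P + rng.normal(0, 0.1, P.shape)
        _, rms = fit_rigid(P, Q)
        oracle = _grid_search_rigid(P, Q, span=0.1)
        assert abs(rms - oracle) < 1e-3
        assert rms <= oracle + 1e-9  # Kabsch is the true minimiser

    def test_collinear_degenerate(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(DegenerateGeometryError):
            fit_rigid(P, P)

    def test_reflection_rejected(self):
        # mirrored points: best proper rotation still has det +1
        P = self._beads().centroids
        Q = P * np.array([1, 1, -1])
        T, _ = fit_rigid(P, Q)
        assert np.linalg.det(T.rotation) == pytest.approx(1.0, abs=1e-9)


class TestBeadSet:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            BeadSet("x", [(0, 0, 0), (0.5, 0, 0), (0, 5, 0)])

    def test_collinear_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            BeadSet("x", [(0, 0, 0), (5, 0, 0), (10, 0, 0)])
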