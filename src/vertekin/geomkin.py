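"""Rigid-body mathematics for vertebral kinematics.

This module provides the pose algebra used everywhere else in the package:
rigid transforms (proper rotation + translation, mm), intrinsic Euler angle
sequences as exported in spine kinematics (Y-X'-Z'' for flexion/extension
trials, X-Z'-Y'' for lateral bending), local coordinate frames built from
implanted-bead triplets or anatomic landmarks, and least-squares rigid
point-set fitting (Kabsch).

Conventions
-----------
* Rotations are 3x3 proper orthonormal matrices; ``transform(p) = R @ p + t``.
* Angles cross the API boundary in degrees; internals work in radians.
* Bead frames: origin at the first bead, x toward the second bead,
  z normal to the bead plane, y completing the right-handed triad.
* Anatomic frames: X positive anteriorly, Y positive left, Z positive
  superiorly, built from one anterior and two lateral landmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "DegenerateGeometryError",
    "GimbalLockWarning",
    "EulerSequence",
    "RigidTransform",
    "EulerAngles",
    "LandmarkSet",
    "BeadSet",
    "frame_from_three_points",
    "anatomic_frame",
    "relative_pose",
    "euler_from_rotation",
    "rotation_from_euler",
    "fit_rigid",
]

_ORTHO_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a point configuration cannot define a frame."""


class GimbalLockWarning(UserWarning):
    """Euler extraction hit the sequence singularity; third angle zeroed."""


class EulerSequence(str, Enum):
    """Intrinsic Euler sequences used for kinematic export.

    ``YXZ`` (Y-X'-Z'') is the flexion/extension export order; ``XZY``
    (X-Z'-Y'') is the lateral-bending export order.  The string value is
    directly consumable by :class:`scipy.spatial.transform.Rotation`
    (uppercase = intrinsic).
    """

    YXZ = "YXZ"
    XZY = "XZY"


def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid transform: ``p_out = rotation @ p_in + translation``.

    rotation is orthonormal with determinant +1 (checked to 1e-9);
    translation is in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.3g})")
        if err > _ORTHO_TOL:
            # re-orthonormalise tiny drift so long compositions stay closed
            U, _, Vt = np.linalg.svd(R)
            R = U @ Vt
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one point or an (n, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        RT = self.rotation.T
        return RigidTransform(RT, -RT @ self.translation)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.rotation, other.rotation, atol=atol)
            and np.allclose(self.translation, other.translation, atol=atol)
        )


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic Euler factorisation of a rotation, angles in degrees.

    ``gimbal_lock`` is set when the middle angle sat at the ±90° singularity
    during extraction; by convention the third angle is then zero.
    """

    sequence: EulerSequence
    angles: np.ndarray
    gimbal_lock: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float).reshape(3)
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite Euler angles")
        # wrap into (-180, 180]
        a = -np.mod(-a + 180.0, 360.0) + 180.0
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "sequence", EulerSequence(self.sequence))


@dataclass(frozen=True)
class LandmarkSet:
    """Anatomic landmarks defining a vertebral anatomic frame.

    ``origin_pt`` is the anterior/superior vertebral body point; ``left_pt``
    and ``right_pt`` are the most lateral/superior points (vertebral notches
    in the cervical spine, vertebral body in the lumbar spine).
    """

    region: str
    origin_pt: np.ndarray
    left_pt: np.ndarray
    right_pt: np.ndarray

    def __post_init__(self) -> None:
        if self.region not in ("cervical", "lumbar"):
            raise ValueError(f"unknown region {self.region!r}")
        for name in ("origin_pt", "left_pt", "right_pt"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )
        area = 0.5 * np.linalg.norm(
            np.cross(self.left_pt - self.origin_pt, self.right_pt - self.origin_pt)
        )
        if area <= 1e-6:
            raise DegenerateGeometryError(
                f"landmarks are collinear (triangle area {area:.3g} mm^2)"
            )


@dataclass(frozen=True)
class BeadSet:
    """Ordered implanted-bead centroids for one vertebral level (mm)."""

    level_id: str
    centroids: np.ndarray
    bead_diameter: float = 1.6

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float).reshape(-1, 3)
        if len(c) < 3:
            raise ValueError(f"need >= 3 beads, got {len(c)}")
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < self.bead_diameter:
            i, j = np.unravel_index(np.argmin(d), d.shape)
            raise ValueError(
                f"beads {i} and {j} of {self.level_id} overlap "
                f"({d.min():.3f} mm < {self.bead_diameter} mm)"
            )
        area = 0.5 * np.linalg.norm(np.cross(c[1] - c[0], c[2] - c[0]))
        if area <= 1e-6:
            raise DegenerateGeometryError(
                f"first three beads of {self.level_id} are collinear"
            )
        object.__setattr__(self, "centroids", c)

    def __len__(self) -> int:
        return len(self.centroids)

    def transformed(self, T: RigidTransform) -> "BeadSet":
        return BeadSet(self.level_id, T.apply(self.centroids), self.bead_diameter)


def frame_from_three_points(p1, p2, p3) -> RigidTransform:
    """Build a local frame from three non-collinear points.

    Origin at ``p1``; x toward ``p2``; z along ``(p2-p1) x (p3-p1)``
    (normal to the point plane); y completes the right-handed triad.
    """
    p1 = np.asarray(p1, dtype=float).reshape(3)
    p2 = np.asarray(p2, dtype=float).reshape(3)
    p3 = np.asarray(p3, dtype=float).reshape(3)
    v12 = p2 - p1
    v13 = p3 - p1
    n = np.cross(v12, v13)
    if np.linalg.norm(n) < 1e-9 or np.linalg.norm(v12) < 1e-12:
        raise DegenerateGeometryError(
            f"points {p1.tolist()}, {p2.tolist()}, {p3.tolist()} are "
            "collinear or coincident; cannot define a frame"
        )
    x = _unit(v12)
    z = _unit(n)
    y = np.cross(z, x)
    return RigidTransform(np.column_stack([x, y, z]), p1)


def anatomic_frame(landmarks: LandmarkSet) -> RigidTransform:
    """Anatomic frame: X anterior, Y left, Z superior.

    Y is the unit left-right axis; X is the origin-to-midpoint direction
    orthogonalised against Y; Z = X x Y gives a right-handed frame.
    """
    y = _unit(landmarks.left_pt - landmarks.right_pt, "left-right axis")
    mid = 0.5 * (landmarks.left_pt + landmarks.right_pt)
    ant = landmarks.origin_pt - mid
    ant = ant - (ant @ y) * y
    if np.linalg.norm(ant) < 1e-9:
        raise DegenerateGeometryError(
            "anterior landmark lies on the left-right axis; anatomic frame undefined"
        )
    x = _unit(ant)
    z = np.cross(x, y)
    return RigidTransform(np.column_stack([x, y, z]), landmarks.origin_pt)


def relative_pose(parent: RigidTransform, child: RigidTransform) -> RigidTransform:
    """Pose of ``child`` expressed in the ``parent`` frame: parent^-1 ∘ child."""
    return parent.inverse().compose(child)


def rotation_from_euler(e: EulerAngles) -> np.ndarray:
    """Rotation matrix from an intrinsic Euler triplet (degrees)."""
    return Rotation.from_euler(e.sequence.value, e.angles, degrees=True).as_matrix()


def euler_from_rotation(R: np.ndarray, sequence: EulerSequence | str) -> EulerAngles:
    """Factor a rotation into an intrinsic Euler triplet (degrees).

    Near the middle-angle singularity (|middle| within ~1e-6 rad of 90°) the
    first/third angles are not unique; the result is returned with the third
    angle zeroed and ``gimbal_lock=True``.
    """
    sequence = EulerSequence(sequence)
    R = np.asarray(R, dtype=float).reshape(3, 3)
    rot = Rotation.from_matrix(R)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy emits its own gimbal warning
        angles = rot.as_euler(sequence.value, degrees=True)
    # scipy already zeroes the third angle at the singularity; detect it
    middle = np.deg2rad(angles[1])
    locked = bool(abs(abs(middle) - np.pi / 2) < 1e-6)
    if locked:
        angles = np.array([angles[0], angles[1], 0.0])
    return EulerAngles(sequence, angles, gimbal_lock=locked)


def fit_rigid(
    reference: BeadSet | np.ndarray, observed: BeadSet | np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform mapping reference points onto observed.

    Kabsch/SVD solution minimising ``sum ||T(ref_i) - obs_i||^2`` with the
    reflection branch rejected (det forced +1).  Returns the transform and
    the RMS residual in mm.
    """
    P = reference.centroids if isinstance(reference, BeadSet) else np.asarray(reference, float)
    Q = observed.centroids if isinstance(observed, BeadSet) else np.asarray(observed, float)
    P = P.reshape(-1, 3)
    Q = Q.reshape(-1, 3)
    if len(P) != len(Q):
        raise ValueError(f"point count mismatch: {len(P)} vs {len(Q)}")
    if len(P) < 3:
        raise ValueError("need >= 3 points for a rigid fit")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, s, Vt = np.linalg.svd(H)
    # collinear configurations leave the in-plane rotation unconstrained
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; rigid fit is degenerate")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    T = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((T.apply(P) - Q) ** 2, axis=-1))))
    return T, rms


# ---------------------------------------------------------------------------
# batched helpers (used by the Monte Carlo engine; same conventions as above)
# ---------------------------------------------------------------------------

def frames_from_three_points_batch(p1, p2, p3):
    """Vectorised :func:`frame_from_three_points`.

    Inputs are (..., 3) stacks; returns rotations (..., 3, 3) with columns
    (x, y, z) and origins (..., 3).  Degenerate entries yield NaN rotations
    (callers check and redraw).
    """
    p1 = np.asarray(p1, float)
    v12 = np.asarray(p2, float) - p1
    n = np.cross(v12, np.asarray(p3, float) - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = v12 / np.linalg.norm(v12, axis=-1, keepdims=True)
        z = n / np.linalg.norm(n, axis=-1, keepdims=True)
    y = np.cross(z, x)
    R = np.stack([x, y, z], axis=-1)
    return R, p1


def fit_rigid_batch(P: np.ndarray, Q: np.ndarray):
    """Vectorised Kabsch: reference (..., n, 3) onto observed (..., n, 3).

    Returns rotations (..., 3, 3) and translations (..., 3).
    """
    cp = P.mean(axis=-2, keepdims=True)
    cq = Q.mean(axis=-2, keepdims=True)
    H = np.swapaxes(P - cp, -1, -2) @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(np.swapaxes(Vt, -1, -2) @ np.swapaxes(U, -1, -2)))
    D = np.zeros(H.shape[:-2] + (3, 3))
    D[..., 0, 0] = 1.0
    D[..., 1, 1] = 1.0
    D[..., 2, 2] = d
    R = np.swapaxes(Vt, -1, -2) @ D @ np.swapaxes(U, -1, -2)
    t = cq[..., 0, :] - np.einsum("...ij,...j->...i", R, cp[..., 0, :])
    return R, t


# ---------------------------------------------------------------------------
# JSON I/O for bead/landmark files
# ---------------------------------------------------------------------------

def load_level_json(path) -> tuple[BeadSet, LandmarkSet | None]:
    """Read one level's beads (and optional landmarks) from JSON.

    Schema: ``{"level": str, "beads": [[x,y,z],...], "landmarks":
    {"origin": [...], "left": [...], "right": [...]}, "units": "mm",
    "region": "cervical"|"lumbar"}``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("units", "mm") != "mm":
        raise ValueError(f"unsupported units {doc.get('units')!r}")
    beads = BeadSet(doc["level"], np.asarray(doc["beads"], float))
    lm = None
    if "landmarks" in doc:
        lmd = doc["landmarks"]
        lm = LandmarkSet(
            doc.get("region", "cervical"), lmd["origin"], lmd["left"], lmd["right"]
        )
    return beads, lm


def dump_level_json(path, beads: BeadSet, landmarks: LandmarkSet | None = None,
                    region: str = "cervical") -> None:
    doc = {
        "level": beads.level_id,
        "beads": beads.centroids.tolist(),
        "units": "mm",
        "region": region,
    }
    if landmarks is not None:
        doc["landmarks"] = {
            "origin": landmarks.origin_pt.tolist(),
            "left": landmarks.left_pt.tolist(),
            "right": landmarks.right_pt.tolist(),
        }
        doc["region"] = landmarks.region
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
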