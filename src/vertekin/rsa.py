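"""Bead-based radiostereometric analysis (RSA).

RSA tracks small implanted tantalum beads (1.6 mm here) in both views of a
biplane rig, reconstructs their 3D positions by stereo triangulation, and
derives each vertebra's rigid pose from its bead cloud.  This module also
implements the rigid validation-block analysis: a machined block carrying
six beads forming two 3-bead coordinate systems with an exactly known
offset; tracking both systems through a dynamic trial and comparing the
observed offset to the known one yields the dynamic bead-tracking error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .geomkin import (
    BeadSet,
    DegenerateGeometryError,
    EulerSequence,
    RigidTransform,
    euler_from_rotation,
    fit_rigid,
    frame_from_three_points,
    relative_pose,
)
from .projection import ProjectionGeometry, RadiographImage, project_point

__all__ = [
    "CameraMatrix",
    "ValidationBlockModel",
    "BeadDetectionError",
    "camera_matrix",
    "detect_bead_centroids",
    "match_points",
    "triangulate",
    "triangulate_beads",
    "beads_to_pose",
    "interbead_distances",
    "validation_block_error",
    "load_validation_block",
]


class BeadDetectionError(RuntimeError):
    """Fewer bead candidates found than expected."""


@dataclass(frozen=True)
class CameraMatrix:
    """3x4 projective matrix mapping homogeneous lab mm to detector pixels.

    Consistent with :func:`vertekin.projection.project_point` to well below
    1e-9 pixels; built exactly (not estimated) from the synthetic geometry.
    """

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, float).reshape(3, 4)
        if np.linalg.matrix_rank(P) != 3:
            raise ValueError("camera matrix must have rank 3")
        object.__setattr__(self, "P", P)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project (n, 3) lab points to (n, 2) pixel (u, v)."""
        p = np.atleast_2d(np.asarray(points, float))
        h = np.hstack([p, np.ones((len(p), 1))]) @ self.P.T
        return h[:, :2] / h[:, 2:3]


def camera_matrix(geom: ProjectionGeometry) -> CameraMatrix:
    """Exact projective matrix of one view of the synthetic rig."""
    n = geom.normal
    S = geom.source
    dc = geom.detector_center
    D = (dc - S) @ n  # source-to-detector distance along the normal
    rows, cols = geom.image_size

    def _row(axis: np.ndarray, center_px: float) -> np.ndarray:
        a = ((S - dc) @ axis) * n + D * axis
        a = a / geom.pixel_pitch + center_px * n
        return np.append(a, -a @ S)

    Pu = _row(geom.detector_u, cols / 2.0)
    Pv = _row(geom.detector_v, rows / 2.0)
    Pw = np.append(n, -n @ S)
    return CameraMatrix(np.vstack([Pu, Pv, Pw]))


def detect_bead_centroids(
    image: RadiographImage,
    expected: int,
    min_separation_px: float = 4.0,
) -> np.ndarray:
    """Detect bright bead projections, sub-pixel, sorted by intensity.

    Otsu threshold, connected components, intensity-weighted centroid per
    component; components closer than ``min_separation_px`` are merged
    (their projections overlap).  Returns exactly ``expected`` points
    ``(u, v)`` ordered by decreasing integrated intensity.
    """
    from scipy import ndimage as ndi
    from skimage.filters import threshold_otsu

    if expected < 1:
        raise ValueError("expected must be >= 1")
    img = image.pixels
    if img.max() <= img.min():
        raise BeadDetectionError("blank image: no bead candidates found (0 components)")
    thr = threshold_otsu(img)
    mask = img > thr
    labels, n = ndi.label(mask)
    if n == 0:
        raise BeadDetectionError("no bead candidates above threshold (0 components)")
    idx = np.arange(1, n + 1)
    # intensity-weighted centroids, background-subtracted weights
    w = np.where(mask, img - thr, 0.0)
    cent = np.array(ndi.center_of_mass(w, labels, idx))  # (n, 2) as (row, col)
    mass = np.array(ndi.sum_labels(w, labels, idx))
    # merge components whose centroids are closer than min_separation_px
    order = np.argsort(-mass)
    kept: list[int] = []
    for i in order:
        merged = False
        for j in kept:
            if np.linalg.norm(cent[i] - cent[j]) < min_separation_px:
                tot = mass[i] + mass[j]
                cent[j] = (cent[j] * mass[j] + cent[i] * mass[i]) / tot
                mass[j] = tot
                merged = True
                break
        if not merged:
            kept.append(i)
    if len(kept) < expected:
        raise BeadDetectionError(
            f"found {len(kept)} bead candidates, expected {expected}"
        )
    kept = sorted(kept, key=lambda i: -mass[i])[:expected]
    # return (u, v) = (col, row)
    return cent[kept][:, ::-1].copy()


def match_points(predicted: np.ndarray, detected: np.ndarray) -> np.ndarray:
    """Greedy one-to-one assignment of detections to predicted positions.

    Used to establish bead correspondence from a prior (the previous
    frame's reconstruction, or projected nominal positions).  Returns the
    permutation ``perm`` such that ``detected[perm[i]]`` corresponds to
    ``predicted[i]``.
    """
    from scipy.optimize import linear_sum_assignment

    predicted = np.atleast_2d(predicted)
    detected = np.atleast_2d(detected)
    if len(detected) < len(predicted):
        raise ValueError("fewer detections than predictions")
    cost = np.linalg.norm(predicted[:, None, :] - detected[None, :, :], axis=-1)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(len(predicted), dtype=int)
    perm[rows] = cols
    return perm


def triangulate(
    camA: CameraMatrix,
    camB: CameraMatrix,
    ptA: Sequence[float],
    ptB: Sequence[float],
) -> tuple[np.ndarray, float]:
    """Linear (DLT) two-view triangulation of one point.

    Returns the 3D point (mm) and the RMS reprojection residual (pixels).
    Raises for near-parallel rays (design-matrix condition number > 1e8).
    """
    uA, vA = ptA
    uB, vB = ptB
    A = np.vstack(
        [
            uA * camA.P[2] - camA.P[0],
            vA * camA.P[2] - camA.P[1],
            uB * camB.P[2] - camB.P[0],
            vB * camB.P[2] - camB.P[1],
        ]
    )
    _, s, Vt = np.linalg.svd(A)
    if s[2] <= 0 or s[0] / s[2] > 1e8:
        raise np.linalg.LinAlgError(
            "ill-conditioned triangulation (near-parallel rays)"
        )
    X = Vt[-1]
    if abs(X[3]) < 1e-15:
        raise np.linalg.LinAlgError("point at infinity in triangulation")
    p = X[:3] / X[3]
    res = np.concatenate([camA.project(p)[0] - (uA, vA), camB.project(p)[0] - (uB, vB)])
    return p, float(np.sqrt(np.mean(res**2)))


def triangulate_beads(
    camA: CameraMatrix,
    camB: CameraMatrix,
    ptsA: np.ndarray,
    ptsB: np.ndarray,
) -> np.ndarray:
    """Triangulate corresponding bead lists; returns (n, 3) mm."""
    ptsA = np.atleast_2d(ptsA)
    ptsB = np.atleast_2d(ptsB)
    if len(ptsA) != len(ptsB):
        raise ValueError("correspondence lists differ in length")
    return np.array([triangulate(camA, camB, a, b)[0] for a, b in zip(ptsA, ptsB)])


def beads_to_pose(
    reference: BeadSet,
    tracked: BeadSet,
    method: str = "three_bead",
) -> RigidTransform:
    """Rigid motion carrying the reference bead cloud onto the tracked one.

    ``three_bead`` composes the local frames built from each set's first
    three beads (the convention used for RSA coordinate systems);
    ``least_squares`` uses the Kabsch fit over all beads.
    """
    if len(reference) != len(tracked):
        raise ValueError("bead count mismatch between reference and tracked sets")
    if method == "three_bead":
        f_ref = frame_from_three_points(*reference.centroids[:3])
        f_trk = frame_from_three_points(*tracked.centroids[:3])
        return f_trk.compose(f_ref.inverse())
    if method == "least_squares":
        T, _ = fit_rigid(reference, tracked)
        return T
    raise ValueError(f"unknown method {method!r}")


def interbead_distances(beads: BeadSet | np.ndarray) -> np.ndarray:
    """All C(n,2) pairwise bead distances, i<j lexicographic order (mm)."""
    c = beads.centroids if isinstance(beads, BeadSet) else np.asarray(beads, float)
    if len(c) < 2:
        raise ValueError("need >= 2 beads")
    i, j = np.triu_indices(len(c), k=1)
    return np.linalg.norm(c[i] - c[j], axis=-1)


@dataclass(frozen=True)
class ValidationBlockModel:
    """Machined 6-bead block defining two frames with a known offset.

    ``frameA_ids``/``frameB_ids`` list the three bead indices building each
    coordinate system (via :func:`frame_from_three_points`); the known
    offset is the pose of frame B expressed in frame A.
    """

    beads: np.ndarray  # (6, 3) mm, block frame
    frameA_ids: tuple[int, int, int]
    frameB_ids: tuple[int, int, int]

    def __post_init__(self) -> None:
        b = np.asarray(self.beads, float).reshape(6, 3)
        object.__setattr__(self, "beads", b)
        object.__setattr__(self, "frameA_ids", tuple(int(i) for i in self.frameA_ids))
        object.__setattr__(self, "frameB_ids", tuple(int(i) for i in self.frameB_ids))
        # constructing the frames validates non-collinearity
        self.frame_a(b)
        self.frame_b(b)

    def frame_a(self, beads: np.ndarray) -> RigidTransform:
        return frame_from_three_points(*beads[list(self.frameA_ids)])

    def frame_b(self, beads: np.ndarray) -> RigidTransform:
        return frame_from_three_points(*beads[list(self.frameB_ids)])

    @property
    def known_offset(self) -> RigidTransform:
        """Frame B in frame A, computed exactly from the bead coordinates."""
        return relative_pose(self.frame_a(self.beads), self.frame_b(self.beads))


def load_validation_block(path=None) -> ValidationBlockModel:
    """Load a validation block model from JSON (default: packaged fixture).

    The packaged block is synthetic: bead coordinates chosen with 12–18 mm
    spacing to mimic vertebral RSA bead placement, not the coordinates of
    any physical block.
    """
    if path is None:
        src = resources.files("vertekin.data").joinpath("validation_block.json")
        doc = json.loads(src.read_text())
    else:
        with open(path) as fh:
            doc = json.load(fh)
    return ValidationBlockModel(
        np.asarray(doc["beads"], float), tuple(doc["frameA_ids"]), tuple(doc["frameB_ids"])
    )


def validation_block_error(
    tracked_beads_per_frame: np.ndarray,
    model: ValidationBlockModel,
    sequence: EulerSequence | str = EulerSequence.YXZ,
):
    """Per-frame known-offset error of the tracked validation block.

    ``tracked_beads_per_frame`` is (n_frames, 6, 3) in model bead order.
    For each frame the two 3-bead frames are rebuilt from the tracked
    coordinates, their observed offset computed, and the error transform
    ``known_offset^-1 ∘ observed_offset`` decomposed into per-axis rotation
    (degrees, intrinsic ``sequence``) and translation (mm) errors.

    Returns a pandas DataFrame with columns ``frame, rot_x/y/z (ordered by
    the sequence's axes), trans_x, trans_y, trans_z, valid``; frames with
    degenerate bead geometry are flagged invalid and carry NaNs.
    """
    import pandas as pd

    tracked = np.asarray(tracked_beads_per_frame, float)
    if tracked.ndim != 3 or tracked.shape[1:] != (6, 3):
        raise ValueError("tracked beads must be (n_frames, 6, 3)")
    seq = EulerSequence(sequence)
    known_inv = model.known_offset.inverse()
    rows = []
    for k, beads in enumerate(tracked):
        try:
            fa = model.frame_a(beads)
            fb = model.frame_b(beads)
            observed = relative_pose(fa, fb)
            err = known_inv.compose(observed)
            ang = euler_from_rotation(err.rotation, seq).angles
            rows.append(
                dict(
                    frame=k,
                    rot_1=ang[0],
                    rot_2=ang[1],
                    rot_3=ang[2],
                    trans_x=err.translation[0],
                    trans_y=err.translation[1],
                    trans_z=err.translation[2],
                    valid=True,
                )
            )
        except DegenerateGeometryError:
            rows.append(
                dict(
                    frame=k,
                    rot_1=np.nan,
                    rot_2=np.nan,
                    rot_3=np.nan,
                    trans_x=np.nan,
                    trans_y=np.nan,
                    trans_z=np.nan,
                    valid=False,
                )
            )
    df = pd.DataFrame(rows)
    df.attrs["sequence"] = seq.value
    return df
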