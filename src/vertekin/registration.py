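"""Automated 2D/3D shape-matching of a bone volume onto biplane radiographs.

The tracker renders DRRs of the bone at a candidate 6-DOF pose, scores them
against the observed biplane images with normalized cross-correlation (NCC),
and maximizes the mean of the two per-view scores with Nelder-Mead simplex
optimization.  A trial is tracked from a single manually placed initial
pose, each frame seeded with the previous frame's optimum, with optional
manual re-initialization frames for the occasional frame the optimizer
cannot carry through.

The pose is parameterized as a 6-vector of offsets relative to the running
pose: 3 translations (mm) and 3 intrinsic rotations (degrees) about the
bone's local axes, so one simplex unit is roughly 1 mm ≈ 1°.  The
parameterization is re-centered at every frame, keeping the simplex
well-conditioned over long trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .geomkin import EulerSequence, RigidTransform
from .projection import (
    ProjectionGeometry,
    RadiographImage,
    Volume,
    render_drr,
    volume_roi,
)

__all__ = [
    "OptimizerSettings",
    "FramePose",
    "TrackingResult",
    "ncc",
    "biplane_objective",
    "register_frame",
    "track_trial",
    "ShapeMatcher",
]


class ConstantImageError(ValueError):
    """NCC is undefined when an image has zero intensity variance."""


def ncc(a: RadiographImage | np.ndarray, b: RadiographImage | np.ndarray) -> float:
    """Pearson-type normalized cross-correlation of two images, in [-1, 1]."""
    x = (a.pixels if isinstance(a, RadiographImage) else np.asarray(a, float)).ravel()
    y = (b.pixels if isinstance(b, RadiographImage) else np.asarray(b, float)).ravel()
    if x.shape != y.shape:
        raise ValueError(f"image size mismatch: {x.shape} vs {y.shape}")
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ConstantImageError("NCC undefined for a constant image")
    return float(np.clip((x @ y) / (nx * ny), -1.0, 1.0))


@dataclass(frozen=True)
class OptimizerSettings:
    """Nelder-Mead configuration for one pose search.

    ``initial_step`` sets the initial simplex extent per component
    (mm for translations, degrees for rotations).  After convergence the
    search is re-launched ``n_restarts`` times from the incumbent with a
    fresh simplex, guarding against premature simplex collapse.
    """

    initial_step: tuple[float, float] = (1.0, 1.0)  # (mm, degrees)
    xatol: float = 1e-4
    fatol: float = 1e-6
    max_iter: int = 500
    n_restarts: int = 2

    def __post_init__(self) -> None:
        if self.xatol <= 0 or self.fatol <= 0:
            raise ValueError("tolerances must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")


@dataclass(frozen=True)
class FramePose:
    """Tracking output for one frame."""

    frame_index: int
    pose: RigidTransform
    score: float
    converged: bool
    reinitialized: bool = False


@dataclass(frozen=True)
class TrackingResult:
    """Per-frame poses and scores for one tracked trial.

    Behaves like a results object: ``poses``/``scores`` arrays, and
    ``summary()`` for a human-readable per-frame table.
    """

    frames: tuple[FramePose, ...]
    fps: float = 60.0
    motion: str = "flexion"

    def __post_init__(self) -> None:
        for f in self.frames:
            if not (-1.0 <= f.score <= 1.0):
                raise ValueError(f"frame {f.frame_index}: NCC score outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def poses(self) -> list[RigidTransform]:
        return [f.pose for f in self.frames]

    @property
    def scores(self) -> np.ndarray:
        return np.array([f.score for f in self.frames])

    @property
    def converged(self) -> np.ndarray:
        return np.array([f.converged for f in self.frames])

    def to_dataframe(self, sequence: EulerSequence | str = EulerSequence.YXZ):
        """Pose table: frame, translations (mm) and Euler angles (degrees)."""
        import pandas as pd

        from .geomkin import euler_from_rotation

        seq = EulerSequence(sequence)
        rows = []
        for f in self.frames:
            e = euler_from_rotation(f.pose.rotation, seq)
            rows.append(
                {
                    "frame": f.frame_index,
                    "tx_mm": f.pose.translation[0],
                    "ty_mm": f.pose.translation[1],
                    "tz_mm": f.pose.translation[2],
                    "e1_deg": e.angles[0],
                    "e2_deg": e.angles[1],
                    "e3_deg": e.angles[2],
                    "sequence": seq.value,
                    "score": f.score,
                    "converged": f.converged,
                    "reinitialized": f.reinitialized,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        s = self.scores
        lines = [
            f"Shape-matching trial ({self.motion}, {len(self)} frames @ {self.fps:g} Hz)",
            f"  NCC score: min {s.min():.4f}  median {np.median(s):.4f}  max {s.max():.4f}",
            f"  converged: {int(self.converged.sum())}/{len(self)}"
            f"  reinitialized: {sum(f.reinitialized for f in self.frames)}",
        ]
        return "\n".join(lines)


def _pose_from_params(base: RigidTransform, q: np.ndarray) -> RigidTransform:
    """Apply a 6-vector offset (tx, ty, tz mm; rx, ry, rz deg) in the bone frame."""
    dR = Rotation.from_euler("XYZ", q[3:6], degrees=True).as_matrix()
    delta = RigidTransform(dR, q[:3])
    return base.compose(delta)


def biplane_objective(
    pose: RigidTransform,
    volume: Volume,
    geoms: Sequence[ProjectionGeometry],
    observed: Sequence[RadiographImage],
    step_mm: float | None = None,
    roi_margin_px: int | None = 8,
    silhouette: bool = True,
) -> float:
    """Mean per-view NCC between rendered DRRs at ``pose`` and the observed pair.

    By default rays are cast only inside the detector window covering the
    posed bone's projected bounding box plus ``roi_margin_px``, and the
    correlation is restricted to the pixels the rendered bone actually
    covers (its silhouette).  Masking matters when several bones share the
    field of view: pixels belonging to un-modelled neighbours would
    otherwise dominate the score and wash out the optimum of the bone being
    tracked.  ``roi_margin_px=None`` with ``silhouette=False`` scores the
    full images.
    """
    if len(geoms) != len(observed):
        raise ValueError("one observed image per view required")
    scores = []
    for geom, obs in zip(geoms, observed):
        if roi_margin_px is None:
            drr = render_drr(volume, pose, geom, step_mm=step_mm)
            obs_px = obs.pixels
            if drr.pixels.shape != obs_px.shape:
                raise ValueError("rendered and observed image sizes differ")
        else:
            if obs.pixels.shape != geom.image_size:
                raise ValueError("observed image size must match the geometry for ROI scoring")
            r0, r1, c0, c1 = volume_roi(geom, volume, pose, roi_margin_px)
            drr = render_drr(volume, pose, geom, step_mm=step_mm, roi=(r0, r1, c0, c1))
            obs_px = obs.pixels[r0:r1, c0:c1]
        if silhouette:
            mask = drr.pixels > 0.0
            if mask.sum() < 32:
                scores.append(-1.0)  # bone (almost) outside the view
                continue
            scores.append(ncc(drr.pixels[mask], obs_px[mask]))
        else:
            scores.append(ncc(drr.pixels, obs_px))
    return float(np.mean(scores))


def register_frame(
    volume: Volume,
    geoms: Sequence[ProjectionGeometry],
    observed: Sequence[RadiographImage],
    init: RigidTransform,
    settings: OptimizerSettings | None = None,
    step_mm: float | None = None,
    roi_margin_px: int | None = 8,
) -> tuple[RigidTransform, float, bool]:
    """Optimize one frame's pose by Nelder-Mead on the biplane NCC objective.

    Returns ``(pose, score, converged)``; on non-convergence within
    ``max_iter`` the best pose found so far is returned with
    ``converged=False``.
    """
    settings = settings or OptimizerSettings()
    base = init

    def cost(q: np.ndarray) -> float:
        return -biplane_objective(
            _pose_from_params(base, q), volume, geoms, observed, step_mm, roi_margin_px
        )

    step_t, step_r = settings.initial_step
    steps = np.array([step_t] * 3 + [step_r] * 3)
    best_pose, best_score, converged = init, -np.inf, True
    for attempt in range(1 + settings.n_restarts):
        q0 = np.zeros(6)
        simplex = np.vstack([q0, q0 + np.diag(steps)])
        res = minimize(
            cost,
            q0,
            method="Nelder-Mead",
            options={
                "initial_simplex": simplex,
                "xatol": settings.xatol,
                "fatol": settings.fatol,
                "maxiter": settings.max_iter,
                "maxfev": 20 * settings.max_iter,
            },
        )
        score = -float(res.fun)
        if score > best_score:
            best_score = score
            best_pose = _pose_from_params(base, res.x)
        converged = converged and bool(res.success)
        base = best_pose  # re-center; next restart perturbs around the incumbent
    return best_pose, best_score, converged


def track_trial(
    volume: Volume,
    geoms: Sequence[ProjectionGeometry],
    frames: Sequence[Sequence[RadiographImage]],
    init_pose: RigidTransform,
    reinit: Mapping[int, RigidTransform] | None = None,
    settings: OptimizerSettings | None = None,
    step_mm: float | None = None,
    roi_margin_px: int | None = 8,
    fps: float = 60.0,
    motion: str = "flexion",
    score_drop: float = 0.1,
    progress: Callable[[int, FramePose], None] | None = None,
) -> TrackingResult:
    """Track a bone through a biplane image sequence.

    ``frames[k]`` is the biplane image pair of frame ``k``.  Frame 0 starts
    from ``init_pose``; frame ``k`` starts from frame ``k-1``'s optimum
    unless ``k`` is in ``reinit`` (a manually set pose, flagged
    ``reinitialized``).  A frame whose score falls more than ``score_drop``
    below the running median of previous scores is flagged unconverged —
    the automated analogue of the visual-inspection step that catches
    frames needing manual shape-matching.
    """
    if len(frames) == 0:
        raise ValueError("empty trial")
    if init_pose is None:
        raise ValueError("an initial pose for frame 0 is required")
    reinit = dict(reinit or {})
    out: list[FramePose] = []
    current = init_pose
    for k, pair in enumerate(frames):
        reinitialized = k in reinit
        if reinitialized:
            current = reinit[k]
        pose, score, conv = register_frame(
            volume, geoms, pair, current, settings, step_mm, roi_margin_px
        )
        if out:
            prev = np.median([f.score for f in out])
            if score < prev - score_drop:
                conv = False
        fp = FramePose(k, pose, score, conv, reinitialized)
        out.append(fp)
        current = pose
        if progress is not None:
            progress(k, fp)
    return TrackingResult(tuple(out), fps=fps, motion=motion)


class ShapeMatcher:
    """Model object for 2D/3D shape-matching of one bone.

    Built from the bone's attenuation volume, the biplane geometry, and the
    observed image sequence; :meth:`fit` runs the tracker and returns a
    :class:`TrackingResult`.

    Parameters
    ----------
    volume : Volume
        Bone attenuation volume (beads masked if implanted).
    geoms : pair of ProjectionGeometry
        Calibrated biplane rig.
    frames : sequence of biplane image pairs
        ``frames[k][i]`` is the frame-``k`` image of view ``i``.
    settings : OptimizerSettings, optional
    step_mm : float, optional
        DRR ray-sampling step; default half the smallest voxel spacing.
    """

    def __init__(
        self,
        volume: Volume,
        geoms: Sequence[ProjectionGeometry],
        frames: Sequence[Sequence[RadiographImage]],
        settings: OptimizerSettings | None = None,
        step_mm: float | None = None,
        roi_margin_px: int | None = 8,
        fps: float = 60.0,
        motion: str = "flexion",
    ) -> None:
        self.volume = volume
        self.geoms = tuple(geoms)
        self.frames = list(frames)
        self.settings = settings or OptimizerSettings()
        self.step_mm = step_mm
        self.roi_margin_px = roi_margin_px
        self.fps = fps
        self.motion = motion

    def score(self, pose: RigidTransform, frame: int = 0) -> float:
        """Biplane NCC objective at an arbitrary pose (diagnostic)."""
        return biplane_objective(
            pose, self.volume, self.geoms, self.frames[frame], self.step_mm, self.roi_margin_px
        )

    def fit(
        self,
        init_pose: RigidTransform,
        reinit: Mapping[int, RigidTransform] | None = None,
        progress: Callable[[int, FramePose], None] | None = None,
    ) -> TrackingResult:
        return track_trial(
            self.volume,
            self.geoms,
            self.frames,
            init_pose,
            reinit=reinit,
            settings=self.settings,
            step_mm=self.step_mm,
            roi_margin_px=self.roi_margin_px,
            fps=self.fps,
            motion=self.motion,
            progress=progress,
        )
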