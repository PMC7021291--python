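"""Synthetic phantoms, motion scripts, and rendered biplane trials.

Everything downstream of image formation is exercised on synthetic data:
a geometric multi-level "cervical spine" phantom (ellipsoidal vertebral
bodies with a cortical shell, posterior-element block, an asymmetric
density knob so axial rotation is identifiable, and four 1.6 mm beads per
level placed anteriorly and spread along the medial-lateral axis), smooth
flexion / lateral-bending motion scripts (smoothstep angle profile, ~25°
range over ~3 s at 60 Hz by default, scaled down for fast tests), rendered
biplane image sequences with ground-truth poses, the rigid validation
block fixture, and a synthetic bead-digitization reliability table.

The phantom is deliberately geometric rather than anatomical: the fidelity
target is enough radiographic structure for the NCC objective to have a
sharp optimum at the true pose, which the loop-closure tests verify.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation

from .geomkin import BeadSet, LandmarkSet, RigidTransform
from .projection import (
    ProjectionGeometry,
    RadiographImage,
    Volume,
    crop_to_content,
    render_drr,
)
from .rsa import ValidationBlockModel, load_validation_block

__all__ = [
    "PhantomSpec",
    "Phantom",
    "MotionScript",
    "cervical_levels",
    "make_phantom",
    "make_motion",
    "render_trial",
    "make_validation_block",
    "simulate_reliability_table",
]

# per-level layout, mm relative to the level center ------------------------

_BODY_HALF_AXES = np.array([8.0, 9.0, 5.5])  # (AP, ML, SI)
_BEADS_REL = np.array(
    [
        [4.0, -6.0, -2.0],
        [4.0, 6.0, -2.0],
        [3.5, -4.0, 2.5],
        [3.5, 5.0, 2.0],
    ]
)
_LANDMARKS_REL = {
    "origin": np.array([7.5, 0.0, 3.5]),  # anterior/superior body
    "left": np.array([0.0, 9.0, 3.0]),
    "right": np.array([0.0, -9.0, 3.0]),
}
_LEVEL_NAMES = ("C4", "C5", "C6")
_LEVEL_SPACING = 16.0  # mm between level centers along SI


def cervical_levels(
    n_levels: int = 3,
    level_spacing: float = _LEVEL_SPACING,
) -> list[tuple[BeadSet, LandmarkSet]]:
    """Packaged synthetic cervical bead/landmark geometry, cranial first.

    Four beads per level on the anterior vertebral body, 10-15 mm spacing
    elongated along the medial-lateral axis (mimicking an anterior surgical
    approach); landmarks follow the anatomic-frame definition (anterior
    origin, left/right lateral points).
    """
    out = []
    z_top = level_spacing * (n_levels - 1) / 2.0
    for i in range(n_levels):
        c = np.array([0.0, 0.0, z_top - i * level_spacing])
        name = _LEVEL_NAMES[i] if i < len(_LEVEL_NAMES) else f"L{i}"
        beads = BeadSet(name, _BEADS_REL + c)
        lm = LandmarkSet(
            "cervical",
            _LANDMARKS_REL["origin"] + c,
            _LANDMARKS_REL["left"] + c,
            _LANDMARKS_REL["right"] + c,
        )
        out.append((beads, lm))
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and attenuation recipe for the synthetic spine phantom.

    Attenuation values are arbitrary linear units per mm and must satisfy
    bead > cortical > trabecular > background.
    """

    levels: int = 3
    shape: tuple[int, int, int] = (96, 96, 96)  # voxels (nx, ny, nz)
    spacing_mm: float = 0.5
    background: float = 0.0
    trabecular: float = 0.3
    cortical: float = 0.8
    bead: float = 4.0
    bead_diameter_mm: float = 1.6
    shell_frac: float = 0.82  # normalised radius where the cortical shell starts
    texture_sd: float = 0.04  # trabecular texture amplitude (attenuation units)

    def __post_init__(self) -> None:
        if not (self.bead > self.cortical > self.trabecular > self.background):
            raise ValueError("need bead > cortical > trabecular > background attenuation")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class Phantom:
    """Synthetic spine phantom: full volume plus per-level pieces.

    ``level_volumes[i]`` contains only level ``i``'s voxels (on the shared
    grid) and is what the shape-matcher renders; ``bead_volumes[i]``
    contains only that level's beads (for RSA bead rendering);
    ``masked_volumes()`` gives per-level volumes with the beads masked out,
    the CT analogue used for DRR generation.
    """

    spec: PhantomSpec
    volume: Volume
    level_volumes: tuple[Volume, ...]
    bead_volumes: tuple[Volume, ...]
    beads: tuple[BeadSet, ...]
    landmarks: tuple[LandmarkSet, ...]

    def masked_volumes(self) -> list[Volume]:
        from .projection import mask_beads

        return [mask_beads(v, b) for v, b in zip(self.level_volumes, self.beads)]


def make_phantom(spec: PhantomSpec | None = None, seed: int = 0) -> Phantom:
    """Build the phantom volume, bead sets and landmark sets.

    The grid is centred on the lab origin.  Beads are rendered as spheres
    with a one-voxel anti-aliased edge so their projected intensity
    centroids are sub-pixel accurate.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.shape
    sp = spec.spacing_mm
    origin = -np.array([nx - 1, ny - 1, nz - 1]) * sp / 2.0
    x = origin[0] + np.arange(nx) * sp
    y = origin[1] + np.arange(ny) * sp
    z = origin[2] + np.arange(nz) * sp
    X = x[None, None, :]
    Y = y[None, :, None]
    Z = z[:, None, None]

    levels = cervical_levels(spec.levels)
    half_extent = np.array([nx, ny, nz]) * sp / 2.0

    level_vox = []
    bead_vox = []
    for li, (beads, _lm) in enumerate(levels):
        c = beads.centroids[0] - _BEADS_REL[0]  # level center
        # adjacent vertebrae are morphologically distinct (as real ones are):
        # body axes, posterior-element extent and knob placement vary with
        # the level index so the shape-matcher cannot lock onto a neighbour
        ax, ay, az = _BODY_HALF_AXES * (1.0 + 0.06 * (li - 1))
        m = np.sqrt(
            ((X - c[0]) / ax) ** 2 + ((Y - c[1]) / ay) ** 2 + ((Z - c[2]) / az) ** 2
        )
        vox = np.zeros((nz, ny, nx))
        vox[m < 1.0] = spec.trabecular
        vox[(m >= spec.shell_frac) & (m < 1.0)] = spec.cortical
        # posterior elements: dense box behind the body
        post = (
            (X - c[0] < -8.0)
            & (X - c[0] > -15.0 + 1.5 * li)
            & (np.abs(Y - c[1]) < 5.0 - 0.8 * li)
            & (np.abs(Z - c[2]) < 4.0 - 0.5 * li)
        )
        vox[np.broadcast_to(post, vox.shape)] = spec.cortical
        # asymmetric knob so axial rotation is identifiable; its azimuth
        # alternates with the level index
        ky = 4.0 if li % 2 == 0 else -4.0
        kz = (li - 1) * 1.5
        knob = (
            (X - (c[0] - 12.0)) ** 2 + (Y - (c[1] + ky)) ** 2 + (Z - (c[2] + kz)) ** 2
            < 3.0**2
        )
        vox[np.broadcast_to(knob, vox.shape)] = spec.cortical
        # trabecular texture (smoothed noise inside the body)
        if spec.texture_sd > 0:
            tex = gaussian_filter(rng.normal(0.0, 1.0, vox.shape), 1.0)
            vox[(m < spec.shell_frac)] += spec.texture_sd * tex[(m < spec.shell_frac)]
        vox = np.clip(vox, 0.0, None)

        bv = np.zeros((nz, ny, nx))
        r = spec.bead_diameter_mm / 2.0
        for b in beads.centroids:
            if np.any(np.abs(b) > half_extent - (r + sp)):
                raise ValueError(f"bead at {b} collides with the volume boundary")
            d = np.sqrt((X - b[0]) ** 2 + (Y - b[1]) ** 2 + (Z - b[2]) ** 2)
            cover = np.clip((r + sp / 2.0 - d) / sp, 0.0, 1.0)
            bv = np.maximum(bv, spec.bead * cover)
        level_vox.append(vox)
        bead_vox.append(bv)

    spacing = np.full(3, sp)
    combined = [np.maximum(v, b) for v, b in zip(level_vox, bead_vox)]
    full = Volume(np.maximum.reduce(combined), spacing, origin)
    level_volumes = tuple(
        crop_to_content(Volume(v, spacing, origin)) for v in combined
    )
    bead_volumes = tuple(
        crop_to_content(Volume(b, spacing, origin)) for b in bead_vox
    )
    return Phantom(
        spec,
        full,
        level_volumes,
        bead_volumes,
        tuple(b for b, _ in levels),
        tuple(lm for _, lm in levels),
    )


@dataclass(frozen=True)
class MotionScript:
    """Ground-truth per-level pose trajectories for one trial.

    ``poses[i][k]`` is level ``i``'s pose at frame ``k`` (volume frame ->
    lab frame).  The angle profile is a cubic smoothstep from 0 to the
    range of motion, the caudal level fixed and motion distributed
    linearly up the column; each moving level rotates about a posterior
    pivot so rotation carries a small, kinematically consistent
    translation arc.
    """

    motion: str  # "flexion" | "lateral_bending"
    fps: float
    duration_s: float
    poses: tuple[tuple[RigidTransform, ...], ...]

    @property
    def n_frames(self) -> int:
        return len(self.poses[0])

    @property
    def n_levels(self) -> int:
        return len(self.poses)

    def to_dataframe(self):
        import pandas as pd

        from .geomkin import euler_from_rotation
        from .trialstats import sequence_for_motion

        seq = sequence_for_motion(self.motion)
        rows = []
        for lvl, series in enumerate(self.poses):
            for k, T in enumerate(series):
                e = euler_from_rotation(T.rotation, seq)
                rows.append(
                    dict(
                        frame=k,
                        level=lvl,
                        tx_mm=T.translation[0],
                        ty_mm=T.translation[1],
                        tz_mm=T.translation[2],
                        e1_deg=e.angles[0],
                        e2_deg=e.angles[1],
                        e3_deg=e.angles[2],
                        sequence=seq.value,
                    )
                )
        return pd.DataFrame(rows)


_MOTION_AXIS = {"flexion": np.array([0.0, 1.0, 0.0]), "lateral_bending": np.array([1.0, 0.0, 0.0])}


def make_motion(
    kind: str = "flexion",
    rom_deg: float = 25.0,
    duration_s: float = 3.0,
    fps: float = 60.0,
    n_levels: int = 3,
    level_spacing: float = _LEVEL_SPACING,
) -> MotionScript:
    """Smoothstep motion script with the caudal level fixed.

    The total (top-vs-bottom) rotation reaches ``rom_deg`` exactly at the
    last frame; peak angular velocity is ``1.5 * rom / duration`` (the
    smoothstep derivative maximum).
    """
    if rom_deg < 0 or duration_s <= 0:
        raise ValueError("rom_deg must be >= 0 and duration_s > 0")
    axis = _MOTION_AXIS.get(kind)
    if axis is None:
        raise ValueError(f"unknown motion kind {kind!r}")
    n_frames = max(2, round(duration_s * fps))
    u = np.linspace(0.0, 1.0, n_frames)
    s = 3 * u**2 - 2 * u**3
    z_top = level_spacing * (n_levels - 1) / 2.0
    poses = []
    for i in range(n_levels):
        frac = (n_levels - 1 - i) / (n_levels - 1) if n_levels > 1 else 1.0
        center = np.array([0.0, 0.0, z_top - i * level_spacing])
        pivot = center + np.array([-10.0, 0.0, 0.0])  # posterior pivot
        series = []
        for sk in s:
            ang = np.deg2rad(frac * rom_deg * sk)
            R = Rotation.from_rotvec(ang * axis).as_matrix()
            t = pivot - R @ pivot
            series.append(RigidTransform(R, t))
        poses.append(tuple(series))
    return MotionScript(kind, fps, duration_s, tuple(poses))


def render_trial(
    phantom: Phantom,
    script: MotionScript,
    geoms: Sequence[ProjectionGeometry],
    noise_sd: float = 0.0,
    seed: int = 0,
    step_mm: float | None = None,
    beads_only: bool = False,
) -> list[tuple[RadiographImage, ...]]:
    """Render the biplane image sequence of a scripted trial.

    Each frame of each view is the sum of the per-level DRRs at the
    scripted poses (line integrals are additive), plus optional additive
    Gaussian pixel noise.  ``beads_only=True`` renders just the bead
    spheres (the RSA view of the trial).
    """
    if script.n_levels != len(phantom.level_volumes):
        raise ValueError("script level count does not match the phantom")
    rng = np.random.default_rng(seed)
    vols = phantom.bead_volumes if beads_only else phantom.level_volumes
    frames = []
    for k in range(script.n_frames):
        pair = []
        for ci, geom in enumerate(geoms):
            acc = None
            for lvl, vol in enumerate(vols):
                img = render_drr(vol, script.poses[lvl][k], geom, step_mm=step_mm)
                acc = img.pixels if acc is None else acc + img.pixels
            if noise_sd > 0:
                acc = acc + rng.normal(0.0, noise_sd, acc.shape)
            pair.append(RadiographImage(acc, geom.pixel_pitch, frame_index=k, camera_id=ci + 1))
        frames.append(tuple(pair))
    return frames


def make_validation_block() -> ValidationBlockModel:
    """The packaged six-bead rigid validation block fixture."""
    return load_validation_block()


def simulate_reliability_table(
    n_raters: int = 5,
    n_sessions: int = 3,
    n_beads: int = 12,
    rater_sd: float = 0.12,
    session_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic bead-digitization reliability table.

    Each rater carries a persistent per-bead, per-axis digitization offset
    drawn from N(0, ``rater_sd``); sessions add independent N(0,
    ``session_sd``) repeat noise.  With negligible session noise the
    interrater SEM estimator recovers ``rater_sd``.
    Returns (raters, sessions, beads, 3) coordinates in mm.
    """
    rng = np.random.default_rng(seed)
    levels = cervical_levels()
    true = np.concatenate([b.centroids for b, _ in levels])[:n_beads]
    if len(true) < n_beads:
        reps = int(np.ceil(n_beads / len(true)))
        true = np.tile(true, (reps, 1))[:n_beads]
    rater_off = rng.normal(0.0, rater_sd, (n_raters, 1, n_beads, 3))
    sess = np.zeros((n_raters, n_sessions, n_beads, 3))
    if session_sd > 0:
        sess = rng.normal(0.0, session_sd, sess.shape)
    return np.broadcast_to(true, (n_raters, n_sessions, n_beads, 3)) + rater_off + sess
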