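"""Volume model, biplane projection geometry, and DRR rendering.

A :class:`Volume` is a 3D attenuation grid (CT stand-in).  A
:class:`ProjectionGeometry` is a point X-ray source plus a planar detector;
two of them arranged around a shared isocenter form a biplane rig (55°
interbeam for the cervical setup, 90° for the lumbar).  :func:`render_drr`
produces a digitally reconstructed radiograph by ray casting: each pixel is
the line integral of trilinearly interpolated attenuation along the ray from
the source through that pixel.

Coordinate conventions (used consistently package-wide)
-------------------------------------------------------
* Lab frame: X anterior, Y left, Z superior; mm.
* Volume voxels are stored as an array indexed ``[iz, iy, ix]`` (x fastest
  in memory); ``origin`` is the lab position of voxel ``[0, 0, 0]``'s center
  and ``spacing = (sx, sy, sz)`` mm.
* Images are ``(rows, cols)`` with the origin at top-left and pixel centers
  at integer coordinates; columns run along ``detector_u``, rows along
  ``detector_v``; the detector center maps to pixel ``(cols/2, rows/2)``
  in (u, v) order.
* The DRR intensity model is a pure line integral — no Beer–Lambert
  exponential — because normalized cross-correlation is invariant to
  monotone linear intensity maps.  An exponential transform is available
  via ``exponential=True`` for visual realism.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence
import warnings

import numpy as np
from scipy.ndimage import map_coordinates

from .geomkin import BeadSet, RigidTransform

__all__ = [
    "Volume",
    "ProjectionGeometry",
    "RadiographImage",
    "make_biplane_geometry",
    "project_point",
    "render_drr",
    "mask_beads",
    "read_volume",
    "write_volume",
    "read_image_stack",
    "write_image_stack",
    "load_geometry_json",
    "dump_geometry_json",
]


@dataclass(frozen=True)
class Volume:
    """3D attenuation grid with voxel spacing and origin (mm), lab frame."""

    voxels: np.ndarray  # indexed [iz, iy, ix]
    spacing: np.ndarray  # (sx, sy, sz) mm/voxel
    origin: np.ndarray  # lab mm position of voxel [0,0,0] center

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or v.size == 0:
            raise ValueError("voxels must be a non-empty 3D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        sp = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(sp <= 0):
            raise ValueError(f"spacing must be positive, got {sp}")
        object.__setattr__(self, "voxels", v)
        object.__setattr__(self, "spacing", sp)
        object.__setattr__(self, "origin", np.asarray(self.origin, float).reshape(3))

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.voxels.shape
        return nx, ny, nz

    def voxel_to_lab(self, ixyz: np.ndarray) -> np.ndarray:
        """Lab coordinates of (possibly fractional) voxel indices (ix,iy,iz)."""
        return self.origin + np.asarray(ixyz, float) * self.spacing

    def center(self) -> np.ndarray:
        return self.voxel_to_lab((np.array(self.shape_xyz, float) - 1) / 2)


@dataclass(frozen=True)
class ProjectionGeometry:
    """Point source + planar detector model for one radiographic view."""

    source: np.ndarray
    detector_center: np.ndarray
    detector_u: np.ndarray  # unit vector along image columns
    detector_v: np.ndarray  # unit vector along image rows
    pixel_pitch: float  # mm
    image_size: tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        for name in ("source", "detector_center", "detector_u", "detector_v"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        u, v = self.detector_u, self.detector_v
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9:
            raise ValueError("detector_u/detector_v must be unit vectors")
        if abs(u @ v) > 1e-9:
            raise ValueError("detector_u and detector_v must be orthogonal")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.sid <= 0:
            raise ValueError("source lies in the detector plane")
        object.__setattr__(self, "image_size", (int(self.image_size[0]), int(self.image_size[1])))

    @property
    def normal(self) -> np.ndarray:
        """Detector plane normal, oriented from source toward detector."""
        n = np.cross(self.detector_u, self.detector_v)
        if n @ (self.detector_center - self.source) < 0:
            n = -n
        return n

    @property
    def sid(self) -> float:
        """Source-to-image distance along the detector normal (mm)."""
        n = np.cross(self.detector_u, self.detector_v)
        return float(abs(n @ (self.detector_center - self.source)))

    def pixel_centers_lab(self, roi: tuple[int, int, int, int] | None = None) -> np.ndarray:
        """(rows, cols, 3) lab coordinates of pixel centers.

        ``roi = (row0, row1, col0, col1)`` restricts to a half-open window.
        """
        rows, cols = self.image_size
        r0, r1, c0, c1 = roi if roi is not None else (0, rows, 0, cols)
        cc = (np.arange(c0, c1) - cols / 2.0) * self.pixel_pitch
        rr = (np.arange(r0, r1) - rows / 2.0) * self.pixel_pitch
        return (
            self.detector_center
            + cc[None, :, None] * self.detector_u
            + rr[:, None, None] * self.detector_v
        )


@dataclass(frozen=True)
class RadiographImage:
    """One radiographic frame (measured or rendered)."""

    pixels: np.ndarray  # (rows, cols)
    pixel_pitch: float
    frame_index: int = 0
    camera_id: int = 1

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2:
            raise ValueError("pixels must be 2D")
        if not np.all(np.isfinite(p)):
            raise ValueError("image contains non-finite pixels")
        object.__setattr__(self, "pixels", p)


def make_biplane_geometry(
    interbeam_deg: float,
    sid_mm: float,
    elevation_deg: float = 0.0,
    pixel_pitch: float = 0.5,
    image_size: tuple[int, int] = (128, 128),
    isocenter: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[ProjectionGeometry, ProjectionGeometry]:
    """Construct a calibrated two-view rig around a common isocenter.

    View 1's central ray runs along the lab +Y (medial-lateral) axis,
    parallel to the horizontal.  View 2's central ray makes exactly
    ``interbeam_deg`` with view 1's and is tilted ``elevation_deg`` above
    the horizontal plane (requires ``elevation_deg <= interbeam_deg``).
    Both central rays pass through the isocenter with the source and
    detector each ``sid_mm / 2`` away, so the isocenter projects to the
    central pixel of both detectors.
    """
    if not (0.0 < interbeam_deg < 180.0):
        raise ValueError(f"interbeam angle must be in (0, 180), got {interbeam_deg}")
    if sid_mm <= 0:
        raise ValueError("sid_mm must be positive")
    ib = np.deg2rad(interbeam_deg)
    el = np.deg2rad(elevation_deg)
    if abs(el) - 1e-12 > ib:
        raise ValueError("elevation cannot exceed the interbeam angle")
    iso = np.asarray(isocenter, float).reshape(3)

    d1 = np.array([0.0, 1.0, 0.0])
    # unit vector perpendicular to d1, tilted so the full ray is elevated by
    # `el` while the angle to d1 stays exactly `ib`
    sphi = np.sin(el) / np.sin(ib)
    phi = np.arcsin(np.clip(sphi, -1.0, 1.0))
    e = np.array([np.cos(phi), 0.0, np.sin(phi)])
    d2 = np.cos(ib) * d1 + np.sin(ib) * e

    def _view(d: np.ndarray) -> ProjectionGeometry:
        up = np.array([0.0, 0.0, 1.0])
        u = np.cross(up, d)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return ProjectionGeometry(
            source=iso - 0.5 * sid_mm * d,
            detector_center=iso + 0.5 * sid_mm * d,
            detector_u=u,
            detector_v=v,
            pixel_pitch=pixel_pitch,
            image_size=image_size,
        )

    return _view(d1), _view(d2)


def project_point(geom: ProjectionGeometry, p) -> tuple[float, float]:
    """Perspective projection of a lab point onto the detector, in pixels.

    Returns ``(u, v)`` with ``u`` along ``detector_u`` (columns) and ``v``
    along ``detector_v`` (rows); the detector center is at
    ``(cols/2, rows/2)``.
    """
    p = np.asarray(p, float).reshape(3)
    n = geom.normal
    d = p - geom.source
    denom = d @ n
    if denom <= 1e-12 * np.linalg.norm(d):
        raise ValueError("point is behind the source or its ray is parallel to the detector")
    k = (geom.detector_center - geom.source) @ n / denom
    q = geom.source + k * d - geom.detector_center
    rows, cols = geom.image_size
    u = q @ geom.detector_u / geom.pixel_pitch + cols / 2.0
    v = q @ geom.detector_v / geom.pixel_pitch + rows / 2.0
    return float(u), float(v)


def render_drr(
    volume: Volume,
    pose: RigidTransform,
    geom: ProjectionGeometry,
    step_mm: float | None = None,
    exponential: bool = False,
    frame_index: int = 0,
    camera_id: int = 1,
    roi: tuple[int, int, int, int] | None = None,
) -> RadiographImage:
    """Ray-cast a digitally reconstructed radiograph of the posed volume.

    ``pose`` maps the volume frame into the lab frame.  Each pixel value is
    the line integral of trilinearly interpolated attenuation from source to
    pixel; samples outside the volume contribute zero.  The integral is
    evaluated with per-ray uniform sampling at approximately ``step_mm``
    (default: half the smallest voxel spacing).  ``roi = (row0, row1, col0,
    col1)`` renders only that detector window (the returned image then has
    the window's size).
    """
    if step_mm is None:
        step_mm = float(volume.spacing.min()) / 2.0
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")

    if roi is None:
        rows, cols = geom.image_size
    else:
        rows, cols = roi[1] - roi[0], roi[3] - roi[2]
        if rows <= 0 or cols <= 0:
            raise ValueError(f"empty ROI {roi}")
    pix = geom.pixel_centers_lab(roi).reshape(-1, 3)
    R, t = pose.rotation, pose.translation
    # ray origins/directions in the volume frame
    src_v = R.T @ (geom.source - t)
    dirs = pix - geom.source
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs_v = dirs @ R  # == (R.T @ dirs.T).T

    # slab intersection with the trilinear-validity box [origin, origin+(n-1)*spacing]
    nx, ny, nz = volume.shape_xyz
    lo = volume.origin
    hi = volume.origin + (np.array([nx, ny, nz]) - 1) * volume.spacing
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - src_v) / dirs_v
        t_hi = (hi - src_v) / dirs_v
    t_near = np.where(np.isfinite(t_lo), np.minimum(t_lo, t_hi), -np.inf)
    t_far = np.where(np.isfinite(t_hi), np.maximum(t_lo, t_hi), np.inf)
    # axes with zero direction: ray inside slab iff origin within bounds
    zero = np.abs(dirs_v) < 1e-15
    inside = (src_v >= lo) & (src_v <= hi)
    t_near = np.where(zero & inside, -np.inf, t_near)
    t_far = np.where(zero & ~inside, -np.inf, t_far)
    t0 = np.maximum(t_near.max(axis=1), 0.0)
    t1 = t_far.min(axis=1)
    hit = t1 > t0

    out = np.zeros(rows * cols)
    if np.any(hit):
        t0h, t1h = t0[hit], t1[hit]
        span = t1h - t0h
        n_steps = max(1, int(np.ceil(span.max() / step_mm)))
        frac = (np.arange(n_steps) + 0.5) / n_steps
        ts = t0h[:, None] + span[:, None] * frac[None, :]
        pts = src_v[None, None, :] + ts[:, :, None] * dirs_v[hit][:, None, :]
        idx = (pts - volume.origin) / volume.spacing  # fractional (ix, iy, iz)
        coords = np.stack([idx[..., 2], idx[..., 1], idx[..., 0]])
        samples = map_coordinates(
            volume.voxels, coords.reshape(3, -1), order=1, mode="constant", cval=0.0
        ).reshape(ts.shape)
        out[hit] = samples.mean(axis=1) * span

    img = out.reshape(rows, cols)
    if exponential:
        img = 1.0 - np.exp(-img)
    return RadiographImage(img, geom.pixel_pitch, frame_index=frame_index, camera_id=camera_id)


def volume_roi(
    geom: ProjectionGeometry,
    volume: Volume,
    pose: RigidTransform,
    margin_px: int = 8,
) -> tuple[int, int, int, int]:
    """Detector window covering the posed volume's bounding box.

    Projects the eight corners of the volume's box and returns the clipped
    pixel bounding rectangle ``(row0, row1, col0, col1)`` with a margin.
    """
    nx, ny, nz = volume.shape_xyz
    ext = (np.array([nx, ny, nz]) - 1) * volume.spacing
    corners = volume.origin + np.array(
        [[i * ext[0], j * ext[1], k * ext[2]] for i in (0, 1) for j in (0, 1) for k in (0, 1)]
    )
    uv = np.array([project_point(geom, pose.apply(c)) for c in corners])
    rows, cols = geom.image_size
    c0 = int(np.floor(uv[:, 0].min())) - margin_px
    c1 = int(np.ceil(uv[:, 0].max())) + margin_px + 1
    r0 = int(np.floor(uv[:, 1].min())) - margin_px
    r1 = int(np.ceil(uv[:, 1].max())) + margin_px + 1
    return max(r0, 0), min(r1, rows), max(c0, 0), min(c1, cols)


def mask_beads(volume: Volume, beads: BeadSet, radius_mm: float | None = None) -> Volume:
    """Replace bead voxels by local background so DRRs are not biased.

    Every voxel within ``radius_mm`` of a bead centroid is replaced by the
    median intensity of the spherical shell between ``radius_mm`` and
    ``2*radius_mm`` around the same centroid, emulating masking of metal
    beads 'consistent with surrounding bone quality'.  Beads lying outside
    the volume are skipped with a warning.
    """
    if radius_mm is None:
        radius_mm = beads.bead_diameter  # half-diameter margin beyond the bead surface
    if radius_mm < beads.bead_diameter / 2:
        raise ValueError("radius_mm must cover the bead radius")
    vox = volume.voxels.copy()
    nx, ny, nz = volume.shape_xyz
    for bi, c in enumerate(beads.centroids):
        idx_c = (c - volume.origin) / volume.spacing
        if np.any(idx_c < 0) or np.any(idx_c > np.array([nx, ny, nz]) - 1):
            warnings.warn(f"bead {bi} of {beads.level_id} lies outside the volume; skipped")
            continue
        r_vox = 2 * radius_mm / volume.spacing  # (x, y, z) half-extents
        x0 = np.maximum(np.floor(idx_c - r_vox).astype(int), 0)
        x1 = np.minimum(np.ceil(idx_c + r_vox).astype(int), np.array([nx, ny, nz]) - 1)
        ix = np.arange(x0[0], x1[0] + 1)
        iy = np.arange(x0[1], x1[1] + 1)
        iz = np.arange(x0[2], x1[2] + 1)
        gx = volume.origin[0] + ix * volume.spacing[0] - c[0]
        gy = volume.origin[1] + iy * volume.spacing[1] - c[1]
        gz = volume.origin[2] + iz * volume.spacing[2] - c[2]
        d2 = (
            gz[:, None, None] ** 2 + gy[None, :, None] ** 2 + gx[None, None, :] ** 2
        )
        sub = vox[x0[2] : x1[2] + 1, x0[1] : x1[1] + 1, x0[0] : x1[0] + 1]
        core = d2 <= radius_mm**2
        shell = (d2 > radius_mm**2) & (d2 <= (2 * radius_mm) ** 2)
        if not shell.any():
            warnings.warn(f"bead {bi} of {beads.level_id}: empty background shell; skipped")
            continue
        sub[core] = np.median(sub[shell])
    return Volume(vox, volume.spacing, volume.origin)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def crop_to_content(volume: Volume, margin_vox: int = 2, threshold: float = 0.0) -> Volume:
    """Crop a volume to the bounding box of voxels above ``threshold``.

    Rendering cost scales with the ray/volume intersection, so tightly
    cropped single-bone volumes register much faster; the origin is
    adjusted so lab-frame positions are unchanged.
    """
    mask = volume.voxels > threshold
    if not mask.any():
        raise ValueError("volume has no content above threshold")
    lo, hi = [], []
    for ax in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != ax))
        idx = np.nonzero(proj)[0]
        lo.append(max(0, idx[0] - margin_vox))
        hi.append(min(mask.shape[ax], idx[-1] + 1 + margin_vox))
    sub = volume.voxels[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    # axes are (z, y, x); origin shift is in (x, y, z)
    shift = np.array([lo[2], lo[1], lo[0]]) * volume.spacing
    return Volume(sub, volume.spacing, volume.origin + shift)


def read_volume(path) -> Volume:
    """Read an MHA/NIfTI volume (via SimpleITK) into lab-frame mm."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    return Volume(
        sitk.GetArrayFromImage(img).astype(float),
        np.asarray(img.GetSpacing()),
        np.asarray(img.GetOrigin()),
    )


def write_volume(path, volume: Volume) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(volume.voxels)
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))


def read_image_stack(path, pixel_pitch: float, camera_id: int = 1) -> list[RadiographImage]:
    """Read a multi-page TIFF as one RadiographImage per frame."""
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return [
        RadiographImage(page.astype(float), pixel_pitch, frame_index=i, camera_id=camera_id)
        for i, page in enumerate(data)
    ]


def write_image_stack(path, images: Sequence[RadiographImage], dtype=np.float32) -> None:
    import tifffile

    stack = np.stack([im.pixels for im in images]).astype(dtype)
    tifffile.imwrite(str(path), stack)


def load_geometry_json(path) -> list[ProjectionGeometry]:
    import json

    with open(path) as fh:
        doc = json.load(fh)
    views = doc["views"] if isinstance(doc, dict) else doc
    return [
        ProjectionGeometry(
            v["source"],
            v["detector_center"],
            v["detector_u"],
            v["detector_v"],
            v["pixel_pitch_mm"],
            tuple(v["image_size"]),
        )
        for v in views
    ]


def dump_geometry_json(path, geoms: Sequence[ProjectionGeometry]) -> None:
    import json

    doc = {
        "views": [
            {
                "source": g.source.tolist(),
                "detector_center": g.detector_center.tolist(),
                "detector_u": g.detector_u.tolist(),
                "detector_v": g.detector_v.tolist(),
                "pixel_pitch_mm": g.pixel_pitch,
                "image_size": list(g.image_size),
            }
            for g in geoms
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
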