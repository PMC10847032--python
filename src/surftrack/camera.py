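"""Virtual stereo-depth cameras: pinhole model, z-buffer rendering, noise.

A :class:`DepthCamera` is a pinhole model (focal lengths and principal point
in pixels) plus a camera-to-room pose.  Rendering rasterizes the phantom
mesh into a per-pixel depth buffer (honoring self-occlusion, e.g. the nose
shadowing a cheek), perturbs each depth along its viewing ray with a
depth-dependent axial noise model, and back-projects valid pixels to a
room-frame surface cloud with grid-based normals.

Camera frame convention: +z along the optical axis, +x to the image right,
+y down; a 3-D point projects to pixel ``u = cx + fx*X/Z``, ``v = cy + fy*Y/Z``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .cloud import SurfaceCloud
from .transforms import RigidTransform

__all__ = [
    "DepthCamera",
    "NoiseModel",
    "look_at",
    "default_cameras",
    "render_depth",
]


@dataclass(frozen=True)
class DepthCamera:
    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    pose: RigidTransform          # camera -> room
    near_mm: float = 100.0
    far_mm: float = 2000.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("resolution must be positive")
        if not 0 < self.near_mm < self.far_mm:
            raise ValueError("need 0 < near < far")

    @staticmethod
    def from_fov(width: int, height: int, fov_x_deg: float, fov_y_deg: float,
                 pose: RigidTransform, **kw) -> "DepthCamera":
        fx = (width / 2.0) / np.tan(np.radians(fov_x_deg) / 2.0)
        fy = (height / 2.0) / np.tan(np.radians(fov_y_deg) / 2.0)
        return DepthCamera(fx, fy, width / 2.0, height / 2.0,
                           width, height, pose, **kw)

    def scaled(self, factor: float) -> "DepthCamera":
        """Same field of view at ``factor`` times the pixel count per axis."""
        return replace(
            self,
            fx=self.fx * factor, fy=self.fy * factor,
            cx=self.cx * factor, cy=self.cy * factor,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
        )

    def intrinsics_dict(self) -> dict:
        return {
            "fx": self.fx, "fy": self.fy, "cx": self.cx, "cy": self.cy,
            "width": self.width, "height": self.height,
            "depth_scale_mm_per_unit": 0.1,
        }


@dataclass(frozen=True)
class NoiseModel:
    """Axial depth noise: Gaussian sigma growing with the square of depth.

    ``sigma(z) = sigma_coeff_mm_per_m2 * (z/1000)^2`` — the stereo-matching
    disparity error maps to a depth error quadratic in range.  The default
    coefficient gives sigma = 1.0 mm at 450 mm.  ``quantization_mm`` rounds
    depths to the sensor's step; ``dropout`` invalidates random pixels.
    """

    sigma_coeff_mm_per_m2: float = 1.0 / 0.45**2
    quantization_mm: float = 0.25
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_coeff_mm_per_m2, self.quantization_mm, self.dropout) < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.dropout >= 1:
            raise ValueError("dropout must be < 1")

    @staticmethod
    def noiseless() -> "NoiseModel":
        return NoiseModel(0.0, 0.0, 0.0)

    @staticmethod
    def from_sigma_at(sigma_mm: float, range_mm: float = 450.0,
                      **kw) -> "NoiseModel":
        return NoiseModel(sigma_mm / (range_mm / 1000.0) ** 2, **kw)

    def sigma_at(self, z_mm: np.ndarray) -> np.ndarray:
        return self.sigma_coeff_mm_per_m2 * (np.asarray(z_mm) / 1000.0) ** 2


def look_at(eye, target, up=(0.0, 0.0, 1.0)) -> RigidTransform:
    """Camera-to-room pose with +z toward ``target`` and +y roughly down."""
    eye = np.asarray(eye, float)
    zc = np.asarray(target, float) - eye
    zc /= np.linalg.norm(zc)
    xc = np.cross(-np.asarray(up, float), zc)
    n = np.linalg.norm(xc)
    if n < 1e-9:
        raise ValueError("view direction is parallel to the up vector")
    xc /= n
    yc = np.cross(zc, xc)
    return RigidTransform(np.column_stack([xc, yc, zc]), eye)


def default_cameras(resolution_scale: float = 1.0) -> list[DepthCamera]:
    """Two couch-mounted cameras flanking the head at ~450 mm range.

    848x480 pixels, 65 x 40 deg field of view, positioned to the patient's
    left and right about 30 cm above the torso plane and inferior of the
    head, looking at the face.  ``resolution_scale`` shrinks the pixel grid
    (same FOV) for fast smaller-scale studies.
    """
    cams = []
    for sx in (+1.0, -1.0):
        pose = look_at(eye=(sx * 300.0, -270.0, 200.0), target=(0.0, 0.0, 40.0))
        cams.append(DepthCamera.from_fov(848, 480, 65.0, 40.0, pose))
    if resolution_scale != 1.0:
        cams = [c.scaled(resolution_scale) for c in cams]
    return cams


@njit(cache=True)
def _rasterize(v_cam, faces, fx, fy, cx, cy, width, height, near, far):
    depth = np.full((height, width), np.inf)
    tri_id = np.full((height, width), -1, np.int32)
    for t in range(faces.shape[0]):
        i0, i1, i2 = faces[t, 0], faces[t, 1], faces[t, 2]
        z0, z1, z2 = v_cam[i0, 2], v_cam[i1, 2], v_cam[i2, 2]
        if z0 <= near or z1 <= near or z2 <= near:
            continue
        if z0 >= far and z1 >= far and z2 >= far:
            continue
        x0 = cx + fx * v_cam[i0, 0] / z0
        y0 = cy + fy * v_cam[i0, 1] / z0
        x1 = cx + fx * v_cam[i1, 0] / z1
        y1 = cy + fy * v_cam[i1, 1] / z1
        x2 = cx + fx * v_cam[i2, 0] / z2
        y2 = cy + fy * v_cam[i2, 1] / z2
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(area) < 1e-12:
            continue
        lo_x = int(np.floor(min(x0, min(x1, x2))))
        hi_x = int(np.ceil(max(x0, max(x1, x2))))
        lo_y = int(np.floor(min(y0, min(y1, y2))))
        hi_y = int(np.ceil(max(y0, max(y1, y2))))
        if lo_x < 0:
            lo_x = 0
        if lo_y < 0:
            lo_y = 0
        if hi_x > width - 1:
            hi_x = width - 1
        if hi_y > height - 1:
            hi_y = height - 1
        if lo_x > hi_x or lo_y > hi_y:
            continue
        inv0, inv1, inv2 = 1.0 / z0, 1.0 / z1, 1.0 / z2
        for py in range(lo_y, hi_y + 1):
            for px in range(lo_x, hi_x + 1):
                w0 = ((x1 - px) * (y2 - py) - (x2 - px) * (y1 - py)) / area
                w1 = ((x2 - px) * (y0 - py) - (x0 - px) * (y2 - py)) / area
                w2 = 1.0 - w0 - w1
                if w0 < -1e-9 or w1 < -1e-9 or w2 < -1e-9:
                    continue
                # perspective-correct depth: 1/z interpolates linearly
                z = 1.0 / (w0 * inv0 + w1 * inv1 + w2 * inv2)
                if near < z < far and z < depth[py, px]:
                    depth[py, px] = z
                    tri_id[py, px] = t
    return depth, tri_id


def render_depth(
    vertices_room: np.ndarray,
    faces: np.ndarray,
    cam: DepthCamera,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    face_labels: np.ndarray | None = None,
    normal_stencil_px: int = 3,
    return_buffers: bool = False,
):
    """Render a posed mesh to a room-frame surface cloud (one point per pixel).

    Self-occlusion is honored by the z-buffer; depths are perturbed along
    the viewing ray by ``noise`` and back-projected through ``cam.pose``.
    Normals come from central differences of the back-projected point grid
    (stencil ``normal_stencil_px`` pixels) oriented toward the camera; pixels
    at depth discontinuities or image borders get ``valid=False`` normals.

    Returns the cloud, or ``(cloud, depth_mm, tri_id)`` if ``return_buffers``
    — the depth buffer is the *recorded* (noise-applied) one, with NaN at
    missed or dropped pixels.
    """
    noise = noise or NoiseModel.noiseless()
    if rng is None:
        rng = np.random.default_rng(noise.seed)

    v_cam = cam.pose.inverse().apply(np.asarray(vertices_room, float))
    depth, tri_id = _rasterize(
        np.ascontiguousarray(v_cam),
        np.ascontiguousarray(np.asarray(faces, np.int64)),
        cam.fx, cam.fy, cam.cx, cam.cy,
        cam.width, cam.height, cam.near_mm, cam.far_mm,
    )
    hit = np.isfinite(depth)
    if not hit.any():
        import warnings

        warnings.warn("mesh entirely outside the camera frustum", stacklevel=2)
        return (SurfaceCloud(np.zeros((0, 3))), depth, tri_id) if return_buffers \
            else SurfaceCloud(np.zeros((0, 3)))

    z = depth.copy()
    if noise.sigma_coeff_mm_per_m2 > 0:
        z[hit] += rng.standard_normal(hit.sum()) * noise.sigma_at(z[hit])
    if noise.quantization_mm > 0:
        z[hit] = np.round(z[hit] / noise.quantization_mm) * noise.quantization_mm
    if noise.dropout > 0:
        drop = rng.random(hit.sum()) < noise.dropout
        idx = np.flatnonzero(hit.reshape(-1))[drop]
        hit.reshape(-1)[idx] = False
    z[~hit] = np.nan

    u = np.arange(cam.width)[None, :]
    v = np.arange(cam.height)[:, None]
    X = (u - cam.cx) * z / cam.fx
    Y = (v - cam.cy) * z / cam.fy
    P = np.stack([X, Y, z], axis=-1)  # camera-frame point grid

    s = normal_stencil_px
    grid_n = np.full_like(P, np.nan)
    inner = np.s_[s:-s, s:-s]
    du = P[s:-s, 2 * s:] - P[s:-s, :-2 * s]
    dv = P[2 * s:, s:-s] - P[:-2 * s, s:-s]
    grid_n[inner] = np.cross(du, dv)

    # validity: pixel + stencil neighbors hit, and no depth discontinuity
    ok = hit.copy()
    nb_ok = np.zeros_like(hit)
    nb_ok[inner] = (hit[s:-s, 2 * s:] & hit[s:-s, :-2 * s]
                    & hit[2 * s:, s:-s] & hit[:-2 * s, s:-s])
    jump_tol = 8.0 + 10.0 * float(np.nanmax(noise.sigma_at(np.nanmax(z[hit]))))
    jump = np.zeros_like(depth)
    jump[inner] = np.maximum(
        np.abs(np.where(np.isfinite(depth[s:-s, 2 * s:]), depth[s:-s, 2 * s:], 0)
               - np.where(np.isfinite(depth[s:-s, :-2 * s]), depth[s:-s, :-2 * s], 0)),
        np.abs(np.where(np.isfinite(depth[2 * s:, s:-s]), depth[2 * s:, s:-s], 0)
               - np.where(np.isfinite(depth[:-2 * s, s:-s]), depth[:-2 * s, s:-s], 0)),
    )
    normal_ok = ok & nb_ok & (jump < jump_tol)

    pts_cam = P[hit]
    n_cam = grid_n[hit]
    valid = normal_ok[hit]
    norm = np.linalg.norm(n_cam, axis=1)
    good = np.isfinite(norm) & (norm > 1e-12)
    valid &= good
    n_unit = np.zeros_like(n_cam)
    n_unit[good] = n_cam[good] / norm[good, None]
    flip = np.einsum("ij,ij->i", n_unit, pts_cam) > 0
    n_unit[flip] *= -1

    labels = None
    if face_labels is not None:
        labels = np.asarray(face_labels)[tri_id[hit]]

    cloud = SurfaceCloud(
        cam.pose.apply(pts_cam),
        cam.pose.rotate(n_unit),
        valid,
        labels,
    )
    if return_buffers:
        return cloud, z, tri_id
    return cloud
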