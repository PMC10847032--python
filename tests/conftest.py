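"""Shared fixtures: small phantoms, scaled cameras, rendered cloud pairs.

Simulation fixtures run at reduced camera resolution and coarser phantom
meshes than the defaults so the suite stays fast; the physics (projection,
occlusion, noise, registration) is identical at any scale.
"""

from __future__ import annotations

import numpy as np
import pytest

from surftrack.camera import NoiseModel, default_cameras, render_depth
from surftrack.cloud import SurfaceCloud
from surftrack.phantom import HeadPhantomParams, make_phantom
from surftrack.transforms import RigidTransform


@pytest.fixture(scope="session")
def phantom_small():
    """Coarser head mesh (~10k triangles) for fast rendering in tests."""
    return make_phantom(HeadPhantomParams(n_lat=71, n_lon=72), seed=7)


@pytest.fixture(scope="session")
def cams_small():
    """The two default cameras at 35% resolution (same fields of view)."""
    return default_cameras(resolution_scale=0.35)


@pytest.fixture(scope="session")
def render_frame(phantom_small, cams_small):
    """Callable rendering the small phantom at a pose into a fused cloud."""

    def _render(pose: RigidTransform, noise: NoiseModel | None = None,
                seed: int = 0) -> SurfaceCloud:
        noise = noise or NoiseModel.noiseless()
        clouds = []
        for j, cam in enumerate(cams_small):
            clouds.append(render_depth(
                pose.apply(phantom_small.vertices), phantom_small.faces,
                cam, noise, np.random.default_rng([seed, j]),
                face_labels=phantom_small.face_labels))
        return SurfaceCloud.concatenate(clouds)

    return _render


@pytest.fixture(scope="session")
def reference_cloud(render_frame):
    """Noise-free fused rendering of the phantom at its home pose."""
    return render_frame(RigidTransform.identity())


def planar_cloud(nx: int, ny: int, pitch_mm: float, *, normals: bool = False,
                 z: float = 0.0) -> SurfaceCloud:
    """Regular grid on the z-plane; handy analytic target for downsampling."""
    x = (np.arange(nx) - (nx - 1) / 2) * pitch_mm
    y = (np.arange(ny) - (ny - 1) / 2) * pitch_mm
    X, Y = np.meshgrid(x, y)
    pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, z)])
    n = None
    if normals:
        n = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return SurfaceCloud(pts, n)


def random_rigid(rng: np.random.Generator, t_scale: float = 50.0) -> RigidTransform:
    """Uniformly random rotation (QR of a Gaussian matrix) + random shift."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return RigidTransform(q, rng.uniform(-t_scale, t_scale, 3))
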