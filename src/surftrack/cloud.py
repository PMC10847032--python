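"""Point-cloud container, ROI cropping, normal estimation and downsampling.

A :class:`SurfaceCloud` holds points in mm with optional per-point unit
normals and validity flags; a point is *valid* when its normal (if any) was
estimated from a well-conditioned neighborhood.  Registration only consumes
valid points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .transforms import RigidTransform

__all__ = [
    "SurfaceCloud",
    "RegionOfInterest",
    "EmptyCloudError",
    "transform_cloud",
    "estimate_normals",
    "crop",
    "downsample",
    "voxel_edge_mm",
]

log = logging.getLogger(__name__)


class EmptyCloudError(ValueError):
    """An operation that requires points was called on an empty cloud."""


@dataclass
class SurfaceCloud:
    """3-D surface samples: ``points`` (N, 3) mm, optional unit ``normals``.

    ``valid`` flags points whose normals are trustworthy; ``labels`` carries
    optional integer anatomy-region codes (used by the simulator).
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.size == 0:
            self.points = self.points.reshape(0, 3)
        if self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        n = len(self.points)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(n, 3)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool).reshape(n)
        if self.labels is not None:
            self.labels = np.asarray(self.labels).reshape(n)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def select(self, mask: np.ndarray) -> "SurfaceCloud":
        """Sub-cloud keeping attributes aligned with their points."""
        return SurfaceCloud(
            self.points[mask],
            None if self.normals is None else self.normals[mask],
            self.valid[mask],
            None if self.labels is None else self.labels[mask],
        )

    def valid_only(self) -> "SurfaceCloud":
        return self.select(self.valid)

    def copy(self) -> "SurfaceCloud":
        return SurfaceCloud(
            self.points.copy(),
            None if self.normals is None else self.normals.copy(),
            self.valid.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    @staticmethod
    def concatenate(clouds: list["SurfaceCloud"]) -> "SurfaceCloud":
        if not clouds:
            return SurfaceCloud(np.zeros((0, 3)))
        points = np.vstack([c.points for c in clouds])
        if all(c.normals is not None for c in clouds):
            normals = np.vstack([c.normals for c in clouds])
        else:
            normals = None
        valid = np.concatenate([c.valid for c in clouds])
        if all(c.labels is not None for c in clouds):
            labels = np.concatenate([c.labels for c in clouds])
        else:
            labels = None
        return SurfaceCloud(points, normals, valid, labels)


@dataclass
class RegionOfInterest:
    """Oriented box: ``center`` (mm), ``half_extents`` (mm), ``orientation``.

    A point is inside iff its coordinates in the box frame lie within
    ±half_extents (closed interval).  The box is oriented (not axis-aligned)
    so rotational ROI propagation during tracking is exact.
    """

    center: np.ndarray
    half_extents: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.half_extents = np.asarray(self.half_extents, dtype=float).reshape(3)
        if np.any(self.half_extents <= 0):
            raise ValueError("ROI half-extents must be strictly positive")
        R = np.asarray(self.orientation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("ROI orientation must be orthonormal")
        self.orientation = R

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed box."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        local = (p - self.center) @ self.orientation
        return np.all(np.abs(local) <= self.half_extents, axis=1)


def transform_cloud(t: RigidTransform, cloud: SurfaceCloud) -> SurfaceCloud:
    """Rigidly move a cloud: points rotated then translated, normals rotated."""
    return SurfaceCloud(
        t.apply(cloud.points),
        None if cloud.normals is None else t.rotate(cloud.normals),
        cloud.valid.copy(),
        None if cloud.labels is None else cloud.labels.copy(),
    )


def estimate_normals(
    cloud: SurfaceCloud,
    k: int = 30,
    viewpoint: np.ndarray | None = None,
) -> SurfaceCloud:
    """Per-point normals from k-NN PCA, sign-flipped to face ``viewpoint``.

    The normal at each point is the eigenvector of the neighborhood
    covariance with the smallest eigenvalue.  Neighborhoods that are
    numerically collinear (two near-zero eigenvalues) yield no usable normal:
    those points are flagged invalid and excluded from registration.
    """
    n = len(cloud)
    if n == 0:
        raise EmptyCloudError("cannot estimate normals of an empty cloud")
    if k < 3:
        raise ValueError("k must be >= 3")
    if n <= k:
        raise ValueError(f"need more than k={k} points, have {n}")
    if viewpoint is None:
        viewpoint = np.zeros(3)
    viewpoint = np.asarray(viewpoint, dtype=float).reshape(3)

    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k)
    nbrs = cloud.points[idx]  # (N, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / k
    evals, evecs = np.linalg.eigh(cov)  # ascending
    normals = evecs[:, :, 0]
    # Collinear neighborhood: the two smallest eigenvalues both vanish.
    scale = np.maximum(evals[:, 2], np.finfo(float).tiny)
    degenerate = evals[:, 1] / scale < 1e-8

    to_view = viewpoint - cloud.points
    flip = np.einsum("ni,ni->n", normals, to_view) < 0
    normals[flip] *= -1
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)

    valid = cloud.valid & ~degenerate
    return SurfaceCloud(cloud.points.copy(), normals, valid,
                        None if cloud.labels is None else cloud.labels.copy())


def crop(cloud: SurfaceCloud, roi: RegionOfInterest) -> SurfaceCloud:
    """Keep exactly the points inside the closed ROI box."""
    mask = roi.contains(cloud.points) if len(cloud) else np.zeros(0, bool)
    out = cloud.select(mask)
    if len(out) == 0:
        log.warning("ROI crop produced an empty cloud")
    return out


def voxel_edge_mm(density_per_cm2: float) -> float:
    """Voxel edge (mm) whose square-face area holds one point at ``density``."""
    if density_per_cm2 <= 0:
        raise ValueError("density must be positive (points per cm^2)")
    return 10.0 / np.sqrt(density_per_cm2)


def downsample(cloud: SurfaceCloud, density_per_cm2: float) -> SurfaceCloud:
    """Voxel-grid reduction to approximately ``density`` points per cm^2.

    The voxel edge is ``sqrt(1/density)`` (in cm, converted to mm); each
    occupied voxel contributes the centroid of its points and the re-normalized
    mean of their normals.  Accumulation is ordering-independent, so the result
    is deterministic for any permutation of the input.
    """
    edge = voxel_edge_mm(density_per_cm2)
    if len(cloud) == 0:
        raise EmptyCloudError("cannot downsample an empty cloud")

    keys = np.floor(cloud.points / edge).astype(np.int64)
    # Flatten the voxel index to one int64 key (grid extents are bounded by
    # the cloud itself); unique keys are sorted, hence the result is
    # independent of input ordering.
    lo = keys.min(axis=0)
    span = keys.max(axis=0) - lo + 1
    flat = ((keys[:, 0] - lo[0]) * span[1] + (keys[:, 1] - lo[1])) * span[2] \
        + (keys[:, 2] - lo[2])
    uniq, inverse = np.unique(flat, return_inverse=True)
    m = len(uniq)

    counts = np.bincount(inverse, minlength=m).astype(float)
    pts = np.zeros((m, 3))
    for j in range(3):
        pts[:, j] = np.bincount(inverse, weights=cloud.points[:, j], minlength=m)
    pts /= counts[:, None]

    normals = None
    valid = np.ones(m, dtype=bool)
    if cloud.normals is not None:
        acc = np.zeros((m, 3))
        w = cloud.valid.astype(float)
        for j in range(3):
            acc[:, j] = np.bincount(
                inverse, weights=cloud.normals[:, j] * w, minlength=m
            )
        norm = np.linalg.norm(acc, axis=1)
        valid = norm > 1e-9
        normals = np.zeros((m, 3))
        normals[valid] = acc[valid] / norm[valid, None]
    else:
        # A voxel is valid if it holds at least one valid point.
        valid = np.bincount(inverse, weights=cloud.valid.astype(float),
                            minlength=m) > 0

    labels = None
    if cloud.labels is not None:
        # Majority-free cheap choice: label of the first point seen per voxel.
        first = np.full(m, -1, dtype=np.int64)
        order = np.arange(len(cloud))
        # reversed so the lowest original index wins
        first[inverse[order[::-1]]] = order[::-1]
        labels = cloud.labels[first]

    return SurfaceCloud(pts, normals, valid, labels)
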