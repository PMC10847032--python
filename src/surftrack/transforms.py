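"""Rigid-body transforms and the 6-DoF couch-correction parameterization.

The room frame is right-handed with +x toward patient-left (LR), +y superior
(SI) and +z anterior (AP); translations are in mm, rotations in degrees.
Euler angles are extrinsic rotations about the fixed room axes applied in
x -> y -> z order, so the rotation matrix is ``Rz @ Ry @ Rx``.  Clinical
head motion is small (a few degrees), where the ordering convention is a
second-order effect, but it is fixed and documented here because the 6-DoF
output is what a couch-correction system would consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidTransform",
    "SixDoF",
    "GimbalLockError",
    "compose",
    "from_sixdof",
    "to_sixdof",
]

_ORTHO_ATOL = 1e-9


class GimbalLockError(ValueError):
    """Euler extraction attempted at a degenerate (|pitch| = 90 deg) pose."""


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
        raise ValueError("rotation matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("rotation matrix has determinant -1 (reflection)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid map ``x -> R @ x + t`` (rotation dimensionless, t in mm).

    By convention the transform maps reference-surface coordinates toward the
    target (current) surface, so a registration result IS the patient motion
    estimate.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "translation", t)

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_matrix(m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("homogeneous matrix must be 4x4")
        return RigidTransform(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array (or a single 3-vector) of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the map "apply ``other``, then ``self``"."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def orthonormalized(self) -> "RigidTransform":
        """Re-project the rotation onto SO(3) (nearest via SVD)."""
        U, _, Vt = np.linalg.svd(self.rotation)
        R = U @ Vt
        if np.linalg.det(R) < 0:
            U[:, -1] *= -1
            R = U @ Vt
        return RigidTransform(R, self.translation)

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        cos = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))

    def translation_norm(self) -> float:
        return float(np.linalg.norm(self.translation))

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition ``a ∘ b``: apply ``b`` first, then ``a``."""
    return a.compose(b)


@dataclass(frozen=True)
class SixDoF:
    """Translations (mm) along LR/SI/AP and rotations (deg) about LR/SI/AP."""

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.tx, self.ty, self.tz, self.rx, self.ry, self.rz])

    @staticmethod
    def from_array(v: np.ndarray) -> "SixDoF":
        v = np.asarray(v, dtype=float).reshape(6)
        return SixDoF(*v)


def from_sixdof(s: SixDoF) -> RigidTransform:
    """Build the rigid transform for a 6-DoF sample.

    Extrinsic x->y->z convention: ``R = Rz(rz) @ Ry(ry) @ Rx(rx)``.
    """
    R = Rotation.from_euler("xyz", [s.rx, s.ry, s.rz], degrees=True)
    return RigidTransform(R.as_matrix(), [s.tx, s.ty, s.tz])


def to_sixdof(t: RigidTransform) -> SixDoF:
    """Extract 6-DoF parameters; raises :class:`GimbalLockError` at |ry|=90."""
    # For R = Rz Ry Rx, element (2,0) is -sin(ry): the extraction degenerates
    # when |R[2,0]| -> 1.
    if abs(t.rotation[2, 0]) > 1.0 - 1e-9:
        raise GimbalLockError(
            "Euler extraction is degenerate: pitch (ry, about SI) is at ±90 deg"
        )
    rx, ry, rz = Rotation.from_matrix(t.rotation).as_euler("xyz", degrees=True)
    tx, ty, tz = t.translation
    return SixDoF(float(tx), float(ty), float(tz), float(rx), float(ry), float(rz))
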