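"""Sensor-to-room calibration from surveyed fiducials, and two-sensor fusion.

Each depth sensor reports points in its own frame; a set of fiducials with
known room coordinates (a labeled calibration jig) gives point pairs from
which the rigid sensor-to-room map is recovered in closed form (Kabsch/SVD).
The RMS fit residual doubles as the verification metric that the imaging
frame of reference matches the treatment room.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cloud import SurfaceCloud, downsample, transform_cloud
from .transforms import RigidTransform

__all__ = [
    "CalibrationResult",
    "DegenerateFiducialsError",
    "fit_rigid",
    "calibrate",
    "fuse",
]


class DegenerateFiducialsError(ValueError):
    """Fiducial configuration is collinear or otherwise rank-deficient."""


@dataclass
class CalibrationResult:
    sensor_to_room: RigidTransform
    rms_residual: float          # mm
    fiducial_count: int
    passed: bool = True
    worst_fiducial: int | None = None   # index of largest residual
    worst_residual: float = 0.0         # mm

    def report(self, labels: list[str] | None = None) -> str:
        status = "PASS" if self.passed else "FAIL"
        worst = (labels[self.worst_fiducial] if labels is not None
                 else f"#{self.worst_fiducial}")
        return (f"calibration {status}: rms={self.rms_residual:.3f} mm over "
                f"{self.fiducial_count} fiducials; worst {worst} "
                f"({self.worst_residual:.3f} mm)")


def fit_rigid(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Least-squares rigid fit: minimize sum ||fixed_i - T(moving_i)||^2.

    Closed-form Kabsch solution via SVD of the cross-covariance, with the
    proper-rotation (det +1) correction.  Requires >= 3 non-collinear pairs.
    """
    moving = np.asarray(moving, float).reshape(-1, 3)
    fixed = np.asarray(fixed, float).reshape(-1, 3)
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must have equal counts")
    if len(moving) < 3:
        raise ValueError("need at least 3 correspondence pairs")

    cm = moving.mean(axis=0)
    cf = fixed.mean(axis=0)
    H = (fixed - cf).T @ (moving - cm)
    U, s, Vt = np.linalg.svd(H)
    # Collinear points leave the second singular value at zero: rotation
    # about the line is unobservable.
    if s[1] <= 1e-9 * max(s[0], np.finfo(float).tiny):
        raise DegenerateFiducialsError(
            "fiducials are collinear; rigid fit is not unique")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    return RigidTransform(R, cf - R @ cm)


def calibrate(
    measured_fiducials: np.ndarray,
    room_fiducials: np.ndarray,
    threshold: float = 0.5,
) -> CalibrationResult:
    """Fit sensor-to-room and verify the RMS residual against ``threshold`` (mm).

    Correspondence is by ordering (the jig's fiducials carry known labels).
    A result above threshold is returned with ``passed=False`` and the worst
    fiducial identified, so the caller can report or re-measure it.
    """
    t = fit_rigid(measured_fiducials, room_fiducials)
    resid = np.linalg.norm(
        np.asarray(room_fiducials, float) - t.apply(measured_fiducials), axis=1)
    rms = float(np.sqrt(np.mean(resid**2)))
    worst = int(np.argmax(resid))
    return CalibrationResult(
        sensor_to_room=t,
        rms_residual=rms,
        fiducial_count=len(resid),
        passed=rms <= threshold,
        worst_fiducial=worst,
        worst_residual=float(resid[worst]),
    )


def fuse(
    clouds: list[SurfaceCloud],
    calibs: list[CalibrationResult],
    thin_density: float | None = None,
) -> SurfaceCloud:
    """Map each sensor cloud to the room frame and concatenate.

    ``thin_density`` (points/cm^2) optionally removes near-duplicate points
    in overlap regions by voxel reduction at the finest tracking density.
    """
    if len(clouds) != len(calibs):
        raise ValueError(
            f"{len(clouds)} clouds but {len(calibs)} calibrations")
    mapped = [transform_cloud(cal.sensor_to_room, c)
              for c, cal in zip(clouds, calibs)]
    fused = SurfaceCloud.concatenate(mapped)
    if thin_density is not None and len(fused):
        fused = downsample(fused, thin_density)
    return fused
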