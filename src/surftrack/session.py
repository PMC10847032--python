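"""Session simulation: pose the phantom, deform, render, fuse, emit truth.

Replicates a robot-phantom tracking experiment entirely in software: a
motion trace poses the head phantom frame by frame, optional facial
deformations (yawn, smile, frown, swallow) perturb the surface non-rigidly,
each virtual camera renders a noisy depth frame, the per-camera clouds are
fused into the room frame, and the exact commanded trace is returned as
ground truth.

All randomness derives from one session seed; frame k rendered by camera j
uses the sub-generator ``default_rng([seed, k, j])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationResult, fuse
from .camera import DepthCamera, NoiseModel, render_depth
from .cloud import SurfaceCloud, transform_cloud
from .motion import MotionTrace
from .phantom import REGION_CODES, HeadPhantom
from .tracking import FrameSequence
from .transforms import RigidTransform

__all__ = [
    "DEFORMATION_MODES",
    "DeformationEvent",
    "facial_deformation",
    "simulate_session",
]

# per mode: (region codes moved, displacement direction in the local frame,
# default peak amplitude mm)
DEFORMATION_MODES = {
    "yawn": ((REGION_CODES["jaw"],), np.array([0.0, -0.7, -0.7]), 8.0),
    "smile": ((REGION_CODES["cheek_left"], REGION_CODES["cheek_right"]),
              np.array([0.0, 0.6, 0.8]), 4.0),
    "shake-free": ((), np.zeros(3), 0.0),   # head shake is rigid: no deformation
    "frown": ((REGION_CODES["brow"],), np.array([0.0, -0.8, 0.6]), 3.0),
    "swallow": ((REGION_CODES["larynx"],), np.array([0.0, 0.0, 1.0]), 3.0),
}


def _remove_rigid_component(points: np.ndarray, delta: np.ndarray,
                            window: np.ndarray) -> np.ndarray:
    """Project the displacement onto the zero-net-force/torque subspace.

    Subtracts a correction of the form ``w_i * (A + B x (p_i - pbar))`` —
    itself supported only where the window ``w`` is nonzero — chosen so the
    corrected field has zero mean and zero first moment about the centroid.
    With both moments zero the least-squares rigid fit of (cloud, deformed
    cloud) is exactly the identity, while points outside the windowed region
    still do not move at all.
    """
    pbar = points.mean(axis=0)
    r = points - pbar
    w = window

    # unknowns x = [A (3), B (3)]; constraints: sum(delta') = 0, sum(r x delta') = 0
    M = np.zeros((6, 6))
    rhs = np.zeros(6)
    sw = w.sum()
    # d/dA of sum(w*(A + Bxr)) etc.
    M[:3, :3] = np.eye(3) * sw
    S = np.einsum("i,ij->j", w, r)

    def skew(v):
        return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0.0]])

    M[:3, 3:] = -skew(S)          # sum w (B x r) = -sum w (r x B) = -[S]x B
    M[3:, :3] = skew(S)           # sum w (r x A) = [S]x A
    # sum w r x (B x r) = sum w (|r|^2 I - r r^T) B
    M[3:, 3:] = np.einsum("i,ij->", w, r * r) * np.eye(3) \
        - np.einsum("i,ij,ik->jk", w, r, r)
    rhs[:3] = delta.sum(axis=0)
    rhs[3:] = np.cross(r, delta).sum(axis=0)
    x = np.linalg.solve(M, rhs)
    A, B = x[:3], x[3:]
    correction = w[:, None] * (A[None, :] + np.cross(np.broadcast_to(B, r.shape), r,
                                                     axisa=1, axisb=1))
    return delta - correction


def facial_deformation(
    cloud: SurfaceCloud,
    mode: str,
    amplitude_mm: float | None = None,
    phase: float = 0.5,
) -> SurfaceCloud:
    """Non-rigid facial motion on a labeled phantom-local cloud.

    The displacement is a cosine-windowed bump confined to the mode's
    anatomical region (labels required), scaled by a smooth temporal envelope
    ``sin(pi * phase)`` so each motion starts and ends at rest, and projected
    to be free of any rigid component.  The realized peak displacement equals
    ``amplitude * sin(pi*phase)``.
    """
    if mode not in DEFORMATION_MODES:
        raise ValueError(
            f"unknown mode {mode!r}; choose from {sorted(DEFORMATION_MODES)}")
    if cloud.labels is None:
        raise ValueError("facial deformation needs anatomical region labels")
    regions, direction, default_amp = DEFORMATION_MODES[mode]
    amp = default_amp if amplitude_mm is None else float(amplitude_mm)
    envelope = float(np.sin(np.pi * np.clip(phase, 0.0, 1.0)))
    target_peak = amp * envelope
    if target_peak == 0.0 or not regions:
        return cloud.copy()

    mask = np.isin(cloud.labels, regions)
    if not mask.any():
        return cloud.copy()

    pts = cloud.points
    center = pts[mask].mean(axis=0)
    d = np.linalg.norm(pts - center, axis=1)
    radius = np.percentile(d[mask], 95) + 1e-9
    window = np.where(mask, np.cos(np.clip(d / radius, 0, 1) * np.pi / 2) ** 2, 0.0)

    # Blend the mode direction with the outward radial direction so the
    # field varies over the region: a windowed *constant* direction lies
    # entirely inside the rigid-projection basis and would be removed.
    radial = pts / np.maximum(np.linalg.norm(pts, axis=1, keepdims=True), 1e-9)
    bulge = direction[None, :] + 0.8 * radial
    delta = window[:, None] * bulge
    delta = _remove_rigid_component(pts, delta, window)
    peak = np.max(np.linalg.norm(delta, axis=1))
    if peak > 0:
        delta *= target_peak / peak

    out = cloud.copy()
    out.points = pts + delta
    return out


@dataclass(frozen=True)
class DeformationEvent:
    """One facial motion spanning [t_start, t_end) seconds of the session."""

    mode: str
    t_start: float
    t_end: float
    amplitude_mm: float | None = None

    def phase_at(self, t: float) -> float | None:
        if self.t_start <= t < self.t_end:
            return (t - self.t_start) / (self.t_end - self.t_start)
        return None


def simulate_session(
    phantom: HeadPhantom,
    trace: MotionTrace,
    cameras: list[DepthCamera],
    noise: NoiseModel | None = None,
    deformations: list[DeformationEvent] | None = None,
    calibrations: list[CalibrationResult] | None = None,
    background: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
) -> tuple[FrameSequence, MotionTrace]:
    """Render a full tracking session and return (frames, ground truth).

    Per trace sample: pose the phantom, apply any active facial deformation
    (in the phantom-local frame), render from each camera with the noise
    model, fuse the per-sensor clouds (identity calibrations by default, or
    injected mis-calibrations), and emit the frame.  ``background`` is an
    optional static (vertices, faces) mesh — e.g. a couch or headrest — that
    does not move with the phantom.

    The returned truth trace is the commanded trace, passed through exactly.
    """
    noise = noise or NoiseModel.noiseless()
    deformations = deformations or []
    if calibrations is None:
        # perfect calibration: the true camera pose
        calibrations = [CalibrationResult(cam.pose, 0.0, 3) for cam in cameras]
    if len(calibrations) != len(cameras):
        raise ValueError("one calibration per camera required")

    face_labels = phantom.face_labels
    bg_v = bg_f = None
    if background is not None:
        bg_v = np.asarray(background[0], float)
        bg_f = np.asarray(background[1], np.int64)

    clouds: list[SurfaceCloud] = []
    for k in range(len(trace)):
        t_k = trace.transform(k)
        verts = phantom.vertices
        for ev in deformations:
            phase = ev.phase_at(float(trace.t_s[k]))
            if phase is not None:
                local = SurfaceCloud(verts, labels=phantom.labels)
                verts = facial_deformation(
                    local, ev.mode, ev.amplitude_mm, phase).points
        verts_room = t_k.apply(verts)
        faces = phantom.faces
        labels = face_labels
        if bg_v is not None:
            faces = np.vstack([faces, bg_f + len(verts_room)])
            verts_room = np.vstack([verts_room, bg_v])
            labels = np.concatenate(
                [labels, np.full(len(bg_f), -1, dtype=labels.dtype)])

        per_cam = []
        for j, cam in enumerate(cameras):
            rng = np.random.default_rng([seed, k, j])
            # each sensor reports in its own (camera) frame; fusion applies
            # the calibration, which defaults to the true camera pose but can
            # be an injected mis-calibration
            cloud_room = render_depth(verts_room, faces, cam, noise, rng,
                                      face_labels=labels)
            per_cam.append(transform_cloud(cam.pose.inverse(), cloud_room))
        clouds.append(fuse(per_cam, calibrations))

    return FrameSequence(trace.t_s.copy(), clouds), MotionTrace(
        trace.t_s.copy(), trace.sixdof.copy())
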