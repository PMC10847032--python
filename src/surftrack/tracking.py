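"""Sequential surface tracking: adaptive ROI propagation and warm starts.

The tracker registers each incoming frame against a fixed reference surface.
The user-defined ROI applies as-is to the first frame only; for every later
frame the previous motion estimate shifts the ROI so it stays locked to the
same patch of anatomy, and the previous estimate also warm-starts the
multiscale registration.  The ROI for frame k is always derived from the
original ROI and the *total* current estimate (never chained incrementally),
so box-pose drift cannot accumulate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

import numpy as np

from .cloud import RegionOfInterest, SurfaceCloud, crop, estimate_normals
from .motion import MotionTrace
from .registration import (
    DegenerateGeometryError,
    MultiscaleSchedule,
    NoCorrespondencesError,
    ReferencePyramid,
    default_schedule,
    multiscale_register,
)
from .transforms import RigidTransform, to_sixdof

__all__ = ["FrameSequence", "TrackingConfig", "shift_roi", "track"]

log = logging.getLogger(__name__)


@dataclass
class FrameSequence:
    """Time-stamped surface clouds in the room frame (sensors already fused)."""

    t_s: np.ndarray
    clouds: list[SurfaceCloud]

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float).reshape(-1)
        if len(self.t_s) != len(self.clouds):
            raise ValueError("one timestamp per frame required")
        if len(self.t_s) > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.clouds)


@dataclass
class TrackingConfig:
    """Registration settings for a tracking session (YAML-serializable)."""

    densities: tuple[float, ...] = ()
    max_iter: int = 30
    loss_alpha: float = 1.0
    tol_mm: float = 0.01
    tol_deg: float = 0.01
    normal_k: int = 30
    propagate_roi: bool = True      # False = fixed-ROI ablation mode
    warm_start: bool = True

    def schedule(self) -> MultiscaleSchedule:
        if not self.densities:
            return default_schedule(self.max_iter)
        from .cloud import voxel_edge_mm

        return MultiscaleSchedule(tuple(
            (d, 4.0 * voxel_edge_mm(d), self.max_iter) for d in self.densities
        ))

    def to_yaml(self, path: str | Path) -> None:
        data = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @staticmethod
    def from_yaml(path: str | Path) -> "TrackingConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "densities" in data:
            data["densities"] = tuple(data["densities"])
        return TrackingConfig(**data)


def shift_roi(roi: RegionOfInterest, t: RigidTransform) -> RegionOfInterest:
    """Move the ROI rigidly with the patient: center mapped, orientation
    rotated, half-extents unchanged."""
    return RegionOfInterest(
        t.apply(roi.center),
        roi.half_extents.copy(),
        t.rotation @ roi.orientation,
    )


def track(
    frames: FrameSequence,
    reference: SurfaceCloud,
    roi0: RegionOfInterest,
    cfg: TrackingConfig | None = None,
) -> MotionTrace:
    """Track a frame sequence against ``reference``, emitting a 6-DoF trace.

    Frame k is cropped with the ROI derived from the estimate of frame k-1
    (``roi0`` itself for k = 0), registered multiscale with the previous
    estimate as the starting point, and its result re-anchors the ROI.  A
    frame whose crop is empty or whose registration fails carries the
    previous estimate forward with ``converged=False``; tracking continues
    with the last good ROI.
    """
    cfg = cfg or TrackingConfig()
    schedule = cfg.schedule()
    pyramid = ReferencePyramid(reference, schedule)

    t_est = RigidTransform.identity()
    roi = roi0
    n = len(frames)
    sixdof = np.zeros((n, 6))
    converged = np.zeros(n, dtype=bool)
    costs = np.full(n, np.nan)

    for k in range(n):
        cloud = frames.clouds[k]
        target = crop(cloud, roi)
        ok = len(target) > 0
        if ok:
            if target.normals is None:
                target = estimate_normals(target, k=cfg.normal_k)
            init = t_est if cfg.warm_start else RigidTransform.identity()
            try:
                res = multiscale_register(
                    target, pyramid, init=init, schedule=schedule,
                    loss_alpha=cfg.loss_alpha,
                    tol_mm=cfg.tol_mm, tol_deg=cfg.tol_deg,
                )
            except (NoCorrespondencesError, DegenerateGeometryError) as exc:
                log.warning("frame %d registration failed: %s", k, exc)
                ok = False
        else:
            log.warning("frame %d: ROI crop empty, frame flagged lost", k)

        if ok:
            t_est = res.transform
            converged[k] = res.converged
            costs[k] = res.final_cost
            if cfg.propagate_roi:
                roi = shift_roi(roi0, t_est)
        sixdof[k] = to_sixdof(t_est).as_array()

    return MotionTrace(frames.t_s.copy(), sixdof, converged, costs)


def write_run_report(path: str | Path, trace: MotionTrace,
                     cfg: TrackingConfig) -> None:
    """Per-frame diagnostics + config echo as JSON."""
    payload = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in cfg.__dict__.items()},
        "frames": [
            {
                "t_s": float(trace.t_s[k]),
                "sixdof": trace.sixdof[k].tolist(),
                "converged": bool(trace.converged[k])
                if trace.converged is not None else None,
                "final_cost": None
                if trace.final_cost is None or not np.isfinite(trace.final_cost[k])
                else float(trace.final_cost[k]),
            }
            for k in range(len(trace))
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))
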