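"""End-to-end benchmark scenarios: simulate, track, and score in one call.

These builders wire the simulator, tracker and evaluator together exactly as
the accuracy studies use them: a head phantom on a virtual robot sweeps the
single-axis staircase (±5 mm and ±5 deg in unit steps, one axis at a time)
and replays smooth head-motion traces, two couch-mounted depth cameras image
it with depth-dependent noise, and the tracker's output is differenced
against the commanded motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .camera import DepthCamera, NoiseModel, default_cameras
from .cloud import RegionOfInterest
from .evaluation import ErrorTrace, align_and_diff
from .motion import MotionTrace, single_axis_protocol, smooth_trace
from .phantom import HeadPhantom, make_phantom
from .session import DeformationEvent, simulate_session
from .tracking import TrackingConfig, track

__all__ = ["BenchmarkScenario", "default_roi", "run_scenario",
           "staircase_benchmark", "smooth_benchmark", "deformation_benchmark"]


def default_roi() -> RegionOfInterest:
    """Box enclosing the face and most of the head, excluding couch level."""
    return RegionOfInterest(center=(0.0, 0.0, 45.0),
                            half_extents=(95.0, 125.0, 80.0))


@dataclass
class BenchmarkScenario:
    name: str
    trace: MotionTrace
    deformations: list[DeformationEvent] = field(default_factory=list)


def run_scenario(
    scenario: BenchmarkScenario,
    phantom: HeadPhantom | None = None,
    cameras: list[DepthCamera] | None = None,
    noise: NoiseModel | None = None,
    cfg: TrackingConfig | None = None,
    roi: RegionOfInterest | None = None,
    seed: int = 0,
    background: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[MotionTrace, MotionTrace, ErrorTrace]:
    """Simulate the scenario, track it, and return (measured, truth, errors).

    The reference surface is the first frame of the session, so the tracker
    measures motion relative to the first commanded pose; the returned truth
    is re-expressed relative to that pose (``T_k T_0^-1``), which is a no-op
    for traces that start at zero motion.
    """
    phantom = phantom or make_phantom(seed=seed)
    cameras = cameras or default_cameras()
    noise = noise if noise is not None else NoiseModel.from_sigma_at(1.0)
    roi = roi or default_roi()
    cfg = cfg or TrackingConfig()

    frames, truth = simulate_session(
        phantom, scenario.trace, cameras, noise,
        deformations=scenario.deformations, seed=seed,
        background=background,
    )
    reference = frames.clouds[0]
    measured = track(frames, reference, roi, cfg)
    truth = _relative_to_first(truth)
    errors = align_and_diff(measured, truth)
    return measured, truth, errors


def _relative_to_first(truth: MotionTrace) -> MotionTrace:
    """Express every sample relative to the first pose: ``T_k T_0^-1``."""
    from .transforms import to_sixdof

    t0_inv = truth.transform(0).inverse()
    if t0_inv.is_identity(1e-12):
        return truth
    rel = np.array([
        to_sixdof(truth.transform(k) @ t0_inv).as_array()
        for k in range(len(truth))
    ])
    return MotionTrace(truth.t_s.copy(), rel)


def staircase_benchmark(dwell_frames: int = 5) -> BenchmarkScenario:
    """The robot protocol: 66 commanded poses, ±5 mm / ±5 deg in unit steps."""
    return BenchmarkScenario(
        "staircase", single_axis_protocol(dwell_frames=dwell_frames))


def smooth_benchmark(seed: int, duration_s: float = 20.0,
                     amplitude_mm: float = 5.0,
                     amplitude_deg: float = 5.0) -> BenchmarkScenario:
    """A seeded band-limited smooth head-motion trace."""
    return BenchmarkScenario(
        f"smooth_{seed}",
        smooth_trace(duration_s, amplitude_mm, amplitude_deg, seed=seed))


def deformation_benchmark(
    seed: int,
    rigid_s: float = 8.0,
    deform_s: float = 8.0,
    amplitude_mm: float = 2.0,
    amplitude_deg: float = 2.0,
    frame_rate_hz: float = 2.0,
) -> tuple[BenchmarkScenario, list[tuple[str, float, float]]]:
    """Smooth rigid motion followed by the same motion plus facial motions.

    Returns the scenario and labeled (rigid / deformation) time windows for
    segmented error reporting.
    """
    total = rigid_s + deform_s
    trace = smooth_trace(total, amplitude_mm, amplitude_deg, seed=seed,
                         frame_rate_hz=frame_rate_hz)
    third = deform_s / 3.0
    deformations = [
        DeformationEvent("yawn", rigid_s, rigid_s + third, 8.0),
        DeformationEvent("smile", rigid_s + third, rigid_s + 2 * third, 4.0),
        DeformationEvent("frown", rigid_s + 2 * third, rigid_s + deform_s, 3.0),
    ]
    segments = [("rigid", 0.0, rigid_s), ("deformation", rigid_s, total)]
    return BenchmarkScenario(f"deform_{seed}", trace, deformations), segments
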