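"""6-DoF motion traces and the benchmark motion protocols.

A :class:`MotionTrace` is a time-stamped sequence of 6-DoF samples
(translations in mm along LR/SI/AP, rotations in deg about LR/SI/AP).  The
single-axis staircase protocol reproduces the robot benchmark: each axis is
swept in 1 mm (or 1 deg) steps from -5 to +5 one axis at a time, dwelling a
fixed number of frames at each commanded pose.  Smooth traces stand in for
replayed human head-motion recordings: band-limited random 6-DoF signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as stio
from .transforms import RigidTransform, SixDoF, from_sixdof

__all__ = ["MotionTrace", "single_axis_protocol", "smooth_trace"]

AXES = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass
class MotionTrace:
    """Timestamps (s) and (N, 6) samples; optional per-frame diagnostics."""

    t_s: np.ndarray
    sixdof: np.ndarray
    converged: np.ndarray | None = None
    final_cost: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, float).reshape(-1)
        self.sixdof = np.asarray(self.sixdof, float).reshape(len(self.t_s), 6)
        if len(self.t_s) > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.converged is not None:
            self.converged = np.asarray(self.converged, bool).reshape(len(self.t_s))
        if self.final_cost is not None:
            self.final_cost = np.asarray(self.final_cost, float).reshape(len(self.t_s))

    def __len__(self) -> int:
        return len(self.t_s)

    def sample(self, k: int) -> SixDoF:
        return SixDoF.from_array(self.sixdof[k])

    def transform(self, k: int) -> RigidTransform:
        return from_sixdof(self.sample(k))

    def to_csv(self, path: str | Path) -> None:
        stio.write_trace_csv(path, self.t_s, self.sixdof)

    @staticmethod
    def from_csv(path: str | Path) -> "MotionTrace":
        t, s = stio.read_trace_csv(path)
        return MotionTrace(t, s)

    def interpolate(self, t_query: np.ndarray) -> np.ndarray:
        """Linear per-axis interpolation onto ``t_query`` (values clamped
        to the ends outside the trace's span)."""
        t_query = np.asarray(t_query, float)
        out = np.empty((len(t_query), 6))
        for j in range(6):
            out[:, j] = np.interp(t_query, self.t_s, self.sixdof[:, j])
        return out


def single_axis_protocol(
    step_mm: float = 1.0,
    range_mm: float = 5.0,
    step_deg: float = 1.0,
    range_deg: float = 5.0,
    dwell_frames: int = 5,
    frame_dt_s: float = 0.2,
) -> MotionTrace:
    """Staircase sweep: -range..+range in unit steps, one axis at a time.

    With the defaults this visits (2*5+1) positions on each of the 3
    translation and 3 rotation axes = 66 commanded poses, holding each pose
    for ``dwell_frames`` frames.  Consecutive duplicate poses (which occur
    only for degenerate ranges) are collapsed.
    """
    if step_mm <= 0 or step_deg <= 0:
        raise ValueError("steps must be positive")
    if range_mm < 0 or range_deg < 0 or dwell_frames < 1:
        raise ValueError("ranges must be >= 0 and dwell_frames >= 1")

    def sweep(rng: float, step: float) -> np.ndarray:
        n = int(round(rng / step))
        return np.arange(-n, n + 1) * step

    poses: list[np.ndarray] = []
    for axis in range(3):
        for v in sweep(range_mm, step_mm):
            pose = np.zeros(6)
            pose[axis] = v
            poses.append(pose)
    for axis in range(3, 6):
        for v in sweep(range_deg, step_deg):
            pose = np.zeros(6)
            pose[axis] = v
            poses.append(pose)

    deduped: list[np.ndarray] = []
    for pose in poses:
        if not deduped or not np.array_equal(pose, deduped[-1]):
            deduped.append(pose)

    frames = np.repeat(np.asarray(deduped), dwell_frames, axis=0)
    t = np.arange(len(frames)) * frame_dt_s
    return MotionTrace(t, frames)


def smooth_trace(
    duration_s: float,
    amplitude_mm: float = 5.0,
    amplitude_deg: float = 5.0,
    seed: int = 0,
    frame_rate_hz: float = 5.0,
    max_freq_hz: float = 0.5,
    n_components: int = 6,
) -> MotionTrace:
    """Band-limited smooth 6-DoF trace starting at zero motion.

    Each axis is a random sum of sinusoids with frequencies below
    ``max_freq_hz``, shifted to start at zero and rescaled so the realized
    per-axis peak equals the requested amplitude.  Deterministic per seed.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    amps = [amplitude_mm] * 3 + [amplitude_deg] * 3
    sig = np.zeros((len(t), 6))
    for j, amp in enumerate(amps):
        if amp == 0:
            continue
        freqs = rng.uniform(0.05, max_freq_hz, n_components)
        phases = rng.uniform(0, 2 * np.pi, n_components)
        coeffs = rng.uniform(0.2, 1.0, n_components)
        x = np.sum(
            coeffs[None, :] * np.sin(2 * np.pi * freqs[None, :] * t[:, None]
                                     + phases[None, :]),
            axis=1,
        )
        x -= x[0]
        peak = np.max(np.abs(x))
        if peak > 0:
            x *= amp / peak
        sig[:, j] = x
    return MotionTrace(t, sig)
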