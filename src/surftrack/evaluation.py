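"""Tracking-error computation and per-axis summary statistics.

The tracking error is the difference between the motion the tracker measured
and the ground-truth motion trace, per axis.  Ground truth (the denser
signal) is linearly interpolated onto the measurement timestamps.  Rotation
errors are component-wise Euler differences — valid in the small-angle
regime the system operates in (a few degrees) — with the geodesic rotation
angle carried as a diagnostic column.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .motion import AXES, MotionTrace
from .transforms import from_sixdof

__all__ = ["ErrorTrace", "ErrorSummary", "align_and_diff", "summarize",
           "benchmark_report"]


@dataclass
class ErrorTrace:
    """Per-frame, per-axis differences: (N, 6) = mm for t*, deg for r*."""

    t_s: np.ndarray
    errors: np.ndarray            # (N, 6) measured - truth
    geodesic_deg: np.ndarray      # (N,) total rotation-error angle

    def __len__(self) -> int:
        return len(self.t_s)

    def segment(self, t_start: float, t_end: float) -> "ErrorTrace":
        m = (self.t_s >= t_start) & (self.t_s < t_end)
        return ErrorTrace(self.t_s[m], self.errors[m], self.geodesic_deg[m])

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.errors, columns=[f"e_{a}" for a in AXES])
        df.insert(0, "t_s", self.t_s)
        df["geodesic_deg"] = self.geodesic_deg
        return df


@dataclass
class ErrorSummary:
    """Box-plot statistics of one error axis.

    Whiskers extend to the most extreme data within 1.5 interquartile ranges
    of the quartiles (i.e. the 1.5 IQR fences clipped to the data range).
    """

    axis: str
    mean: float
    sd: float
    mean_abs: float
    p25: float
    p50: float
    p75: float
    whisker_lo: float
    whisker_hi: float
    n: int


def align_and_diff(measured: MotionTrace, truth: MotionTrace) -> ErrorTrace:
    """Interpolate truth to the measurement timestamps and subtract."""
    t0 = max(measured.t_s[0], truth.t_s[0])
    t1 = min(measured.t_s[-1], truth.t_s[-1])
    if t1 < t0:
        raise ValueError("measured and truth traces do not overlap in time")
    keep = (measured.t_s >= t0) & (measured.t_s <= t1)
    t = measured.t_s[keep]
    meas = measured.sixdof[keep]
    tru = truth.interpolate(t)
    err = meas - tru

    geo = np.empty(len(t))
    for i in range(len(t)):
        r_m = from_sixdof_rotation(meas[i])
        r_t = from_sixdof_rotation(tru[i])
        delta = r_m @ r_t.T
        cos = np.clip((np.trace(delta) - 1) / 2, -1, 1)
        geo[i] = np.degrees(np.arccos(cos))
    return ErrorTrace(t, err, geo)


def from_sixdof_rotation(sample: np.ndarray) -> np.ndarray:
    from .transforms import SixDoF

    return from_sixdof(SixDoF.from_array(sample)).rotation


def summarize(e: ErrorTrace) -> dict[str, ErrorSummary]:
    """Per-axis mean, sample SD (n-1), quartiles and 1.5 IQR whiskers."""
    if len(e) < 2:
        raise ValueError("need at least 2 samples to summarize (sd undefined)")
    out: dict[str, ErrorSummary] = {}
    for j, axis in enumerate(AXES):
        x = e.errors[:, j]
        p25, p50, p75 = np.percentile(x, [25, 50, 75])
        iqr = p75 - p25
        out[axis] = ErrorSummary(
            axis=axis,
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)),
            mean_abs=float(np.mean(np.abs(x))),
            p25=float(p25), p50=float(p50), p75=float(p75),
            whisker_lo=float(max(x.min(), p25 - 1.5 * iqr)),
            whisker_hi=float(min(x.max(), p75 + 1.5 * iqr)),
            n=len(x),
        )
    return out


def benchmark_report(
    scenarios: dict[str, tuple[MotionTrace, MotionTrace]],
    segments: dict[str, list[tuple[str, float, float]]] | None = None,
    gate_mm: float = 1.0,
    gate_deg: float = 1.0,
    out_dir: str | Path | None = None,
) -> dict:
    """Per-scenario, per-axis error summaries with accuracy-gate verdicts.

    ``scenarios`` maps a name to (measured, truth); ``segments`` optionally
    splits a scenario into labeled time windows (e.g. rigid vs deformation)
    reported as separate rows.  Gates pass when the mean absolute error is
    below ``gate_mm`` / ``gate_deg`` on every translation / rotation axis.
    Writes ``report.json``, ``summary.csv`` and box-plot data if ``out_dir``.
    """
    import warnings

    segments = segments or {}
    rows = []
    report: dict = {"gate_mm": gate_mm, "gate_deg": gate_deg, "scenarios": {}}
    for name, pair in scenarios.items():
        if pair is None:
            warnings.warn(f"scenario {name!r} missing; omitted", stacklevel=2)
            continue
        measured, truth = pair
        err = align_and_diff(measured, truth)
        windows = [("all", err.t_s[0], err.t_s[-1] + 1e-9)]
        windows += segments.get(name, [])
        scen: dict = {}
        for label, t0, t1 in windows:
            seg = err.segment(t0, t1)
            if len(seg) < 2:
                warnings.warn(
                    f"segment {name}/{label} has <2 samples; omitted",
                    stacklevel=2)
                continue
            summ = summarize(seg)
            trans_ok = all(summ[a].mean_abs < gate_mm for a in AXES[:3])
            rot_ok = all(summ[a].mean_abs < gate_deg for a in AXES[3:])
            scen[label] = {
                "summary": {a: asdict(s) for a, s in summ.items()},
                "pass_translation": bool(trans_ok),
                "pass_rotation": bool(rot_ok),
            }
            for a, s in summ.items():
                rows.append({"scenario": name, "segment": label, **asdict(s)})
        report["scenarios"][name] = scen

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1))
        pd.DataFrame(rows).to_csv(out / "summary.csv", index=False)
        box = pd.DataFrame(
            [r for r in rows],
            columns=["scenario", "segment", "axis", "p25", "p50", "p75",
                     "whisker_lo", "whisker_hi", "n"],
        )
        box.to_csv(out / "boxplot_data.csv", index=False)
    return report
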