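"""P-H curve construction and floating/sinking pulse statistics.

The P-H curve plots pulse pressure (P) against hold-down pressure (H): five
measured (APP, pulse-pressure) points joined by a natural cubic spline.
From it the coefficient of floating and sinking pulse is

    CFS = 10 * (X - X_min) / (X_max - X_min),

where X_min and X_max are the actual applied pressures at the first and
last steps and X is the hold-down pressure at which the interpolated curve
peaks.  CFS < 5 is a floating pulse (strongest under light pressure),
CFS >= 5 a sinking pulse.  The alternative "new CFS" statistic is the
weak-minus-strong pulse-pressure contrast

    newCFS = (Y1 + Y2)/2 - (Y4 + Y5)/2   [mmHg],

positive for floating-like curves; it is reported but not used for
classification (a single palpation position does not license the call).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .acquisition import AcquisitionResult, StepRecording
from . import signal_ops

__all__ = [
    "PHCurve",
    "CFSResult",
    "NewCFSResult",
    "build_ph_curve",
    "find_x",
    "cfs",
    "classify_floating_sinking",
    "new_cfs",
    "analyze_result",
]

FLOATING = "floating"
SINKING = "sinking"

#: evaluation grid step for the spline argmax, mmHg
GRID_STEP = 0.1


@dataclass
class PHCurve:
    apps: np.ndarray            # mmHg, strictly increasing
    pulse_pressures: np.ndarray  # mmHg
    spline: CubicSpline
    grid_step: float = GRID_STEP

    @property
    def x_min(self) -> float:
        return float(self.apps[0])

    @property
    def x_max(self) -> float:
        return float(self.apps[-1])


@dataclass(frozen=True)
class CFSResult:
    x_min: float
    x_max: float
    x: float
    cfs: float
    label: str


@dataclass(frozen=True)
class NewCFSResult:
    weak: float     # mmHg, mean pulse pressure of steps 1-2
    strong: float   # mmHg, mean pulse pressure of steps 4-5
    new_cfs: float  # mmHg, weak - strong


def build_ph_curve(apps: np.ndarray, pulse_pressures: np.ndarray) -> PHCurve:
    """Natural cubic spline through the five (APP, pulse pressure) points."""
    a = np.asarray(apps, dtype=float)
    y = np.asarray(pulse_pressures, dtype=float)
    if a.size != y.size or a.size < 2:
        raise ValueError("need matching APP / pulse-pressure arrays (>= 2 points)")
    order = np.argsort(a)
    a, y = a[order], y[order]
    if np.any(np.diff(a) <= 0):
        raise ValueError("duplicate APP values")
    spline = CubicSpline(a, y, bc_type="natural")
    return PHCurve(a, y, spline)


def find_x(curve: PHCurve) -> float:
    """Hold-down pressure of the interpolated maximum pulse pressure.

    Argmax of the spline on a ``grid_step`` grid over [x_min, x_max]; exact
    ties resolve to the lowest pressure.
    """
    n = int(round((curve.x_max - curve.x_min) / curve.grid_step)) + 1
    grid = curve.x_min + curve.grid_step * np.arange(n)
    grid = np.clip(grid, curve.x_min, curve.x_max)
    vals = curve.spline(grid)
    return float(grid[int(np.argmax(vals))])


def cfs(x_min: float, x_max: float, x: float) -> float:
    """Coefficient of floating and sinking pulse, 0 (fully floating) to 10
    (fully sinking)."""
    if x_max <= x_min:
        raise ValueError(f"degenerate pressure range ({x_min}, {x_max})")
    if not (x_min <= x <= x_max):
        raise ValueError(f"X={x} outside [{x_min}, {x_max}]")
    return 10.0 * (x - x_min) / (x_max - x_min)


def classify_floating_sinking(cfs_value: float) -> str:
    """Floating if CFS < 5, sinking if CFS >= 5."""
    if not (0.0 <= cfs_value <= 10.0):
        raise ValueError(f"CFS {cfs_value} outside [0, 10]")
    return SINKING if cfs_value >= 5.0 else FLOATING


def new_cfs(y: np.ndarray) -> NewCFSResult:
    """Weak-minus-strong pulse-pressure contrast from the five step values."""
    y = np.asarray(y, dtype=float)
    if y.size != 5:
        raise ValueError("new CFS needs exactly 5 pulse pressures")
    if np.any(y < 0):
        raise ValueError("pulse pressures must be non-negative")
    weak = float((y[0] + y[1]) / 2.0)
    strong = float((y[3] + y[4]) / 2.0)
    return NewCFSResult(weak=weak, strong=strong, new_cfs=weak - strong)


def analyze_result(
    result: AcquisitionResult,
    min_beat_interval: float = 0.33,
    min_prominence: float = 1.0,
    pulses_per_mm: int = 200,
) -> dict:
    """Full per-subject analysis of one acquisition: P-H curve, X, CFS,
    floating/sinking label, new CFS and moving distance.

    A step recording with no segmentable beats (pulse below the detection
    floor, e.g. a fixed-range step outside the subject's perceptible range)
    contributes a pulse pressure of 0 — the instrument simply feels no
    pulse there.  Returns a plain dict ready for JSON serialization.
    """
    recs: list[StepRecording] = sorted(result.recordings, key=lambda r: r.step_index)
    apps = np.array([r.app for r in recs])

    def _pp(r: StepRecording) -> float:
        try:
            return signal_ops.pulse_pressure(
                r.samples, r.times, min_beat_interval, min_prominence
            )
        except signal_ops.InsufficientBeatsError:
            return 0.0

    ys = np.array([_pp(r) for r in recs])
    curve = build_ph_curve(apps, ys)
    x = find_x(curve)
    c = cfs(curve.x_min, curve.x_max, x)
    nc = new_cfs(ys) if ys.size == 5 else None
    move = abs(recs[-1].motor_position - recs[0].motor_position) / pulses_per_mm
    return {
        "subject_id": result.subject_id,
        "method": result.method,
        "x_min": curve.x_min,
        "x_max": curve.x_max,
        "x": x,
        "cfs": c,
        "label": classify_floating_sinking(c),
        "new_cfs": nc.new_cfs if nc else None,
        "app": apps.tolist(),
        "y": ys.tolist(),
        "moving_distance_mm": move,
    }
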