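"""Protocol engine: simulated motor control and the two measurement protocols.

The simulated instrument presses a single pressure sensor onto a
:class:`~pulsedepth.pulse_model.SubjectProfile` wrist with a step motor
(5 um/pulse by default) and runs either

* the **fixed-range protocol**: fast descent to skin contact, then slow
  descent stopping at 40/90/140/190/240 mmHg, recording 10 s at each; or
* the **adaptive protocol**: a continuous slow descent recording the signal
  until the pulse disappears, beat-peak detection on that sweep to find the
  subject's own perceptible-pressure range, division of that range into five
  equal steps, and measurement of the steps on the way back up (motor up =
  decreasing hold-down pressure).

Motor speeds follow the instrument's fast/slow convention (1.563 and
0.125 mm/s).  All randomness is seeded; identical inputs give bit-identical
results.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .pulse_model import (
    BeatShape,
    SubjectProfile,
    baseline_pressure,
    depth_for_pressure,
    envelope_amplitude,
)
from . import signal_ops

__all__ = [
    "MotorConfig",
    "ProtocolConfig",
    "SweepTrace",
    "StepRecording",
    "AcquisitionResult",
    "NoPulseDetectedError",
    "run_existing_protocol",
    "run_descent_sweep",
    "determine_pressure_range",
    "divide_pressure_range",
    "run_proposed_protocol",
    "moving_distance",
]


class NoPulseDetectedError(RuntimeError):
    """The descent sweep reached the safety pressure without seeing a beat."""


@dataclass(frozen=True)
class MotorConfig:
    fast_speed: float = 1.563       # mm/s, approach speed
    slow_speed: float = 0.125       # mm/s, sweep / servo speed
    pulses_per_mm: int = 200        # step-motor resolution (5 um/pulse)
    sampling_rate: float = 500.0    # Hz
    pressure_tolerance: float = 2.0  # mmHg, servo acceptance band

    def __post_init__(self) -> None:
        if not (self.fast_speed > self.slow_speed > 0):
            raise ValueError("require fast_speed > slow_speed > 0")
        if self.pulses_per_mm <= 0 or self.sampling_rate <= 0:
            raise ValueError("pulses_per_mm and sampling_rate must be > 0")


@dataclass(frozen=True)
class ProtocolConfig:
    n_steps: int = 5
    dwell: float = 10.0                         # s per step
    fixed_step_pressures: tuple[float, ...] = (40.0, 90.0, 140.0, 190.0, 240.0)
    max_pressure: float = 300.0                 # mmHg safety stop
    silence_window: float = 2.0                 # s without a beat ends the sweep
    min_peak_prominence: float = 2.0            # mmHg; the perceptibility floor
    min_beat_interval: float = 0.33             # s (<= 180 bpm)
    contact_threshold: float = 5.0              # mmHg sustained -> skin contact
    contact_sustain: float = 0.02               # s

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.dwell <= 0:
            raise ValueError("dwell must be > 0")
        if np.any(np.diff(self.fixed_step_pressures) <= 0):
            raise ValueError("fixed_step_pressures must be strictly increasing")


@dataclass
class SweepTrace:
    """Continuous record of the adaptive descent (fast approach + slow sweep)."""

    times: np.ndarray
    pressures: np.ndarray
    motor_positions: np.ndarray     # pulses
    phases: np.ndarray              # 'fast-descent' | 'slow-sweep'

    def __post_init__(self) -> None:
        n = len(self.times)
        if not (len(self.pressures) == len(self.motor_positions) == len(self.phases) == n):
            raise ValueError("sweep trace arrays must have equal length")

    @property
    def slow_mask(self) -> np.ndarray:
        return self.phases == "slow-sweep"


@dataclass
class StepRecording:
    """One dwell at one pressure step."""

    step_index: int                 # 1..n_steps, 1 = lowest pressure
    target_pressure: float          # mmHg commanded
    app: float                      # mmHg, mean baseline during the dwell
    motor_position: int             # pulses at hold
    t0: float                       # s, dwell start (instrument clock)
    sampling_rate: float            # Hz
    samples: np.ndarray             # mmHg
    within_tolerance: bool = True

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass
class AcquisitionResult:
    method: str                     # 'existing' | 'proposed'
    subject_id: str
    recordings: list[StepRecording]
    sweep: SweepTrace | None = None
    partial: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        idx = [r.step_index for r in self.recordings]
        if len(set(idx)) != len(idx):
            raise ValueError("duplicate step indices")

    def step(self, index: int) -> StepRecording:
        for r in self.recordings:
            if r.step_index == index:
                return r
        raise KeyError(f"no step {index} in result")

    @property
    def step1_position(self) -> int:
        return self.step(1).motor_position

    @property
    def step5_position(self) -> int:
        return self.step(max(r.step_index for r in self.recordings)).motor_position


class _Instrument:
    """Sample-accurate simulation state: clock, motor depth, sensor noise."""

    def __init__(
        self,
        profile: SubjectProfile,
        motor: MotorConfig,
        proto: ProtocolConfig,
        seed: int,
        beat: BeatShape | None = None,
    ):
        self.profile = profile
        self.motor = motor
        self.proto = proto
        self.beat = beat or BeatShape()
        self.rng = np.random.default_rng(seed)
        self.dt = 1.0 / motor.sampling_rate
        self.sample_count = 0           # instrument clock in samples
        self.depth = 0.0                # mm

    @property
    def time(self) -> float:
        return self.sample_count * self.dt

    def _signal(self, depths: np.ndarray, times: np.ndarray) -> np.ndarray:
        base = baseline_pressure(self.profile, depths)
        amp = envelope_amplitude(self.profile, base)
        phase = self.profile.heart_rate / 60.0 * times
        sig = base + amp * self.beat(phase)
        if self.profile.noise_sd > 0:
            sig = sig + self.rng.normal(0.0, self.profile.noise_sd, size=sig.shape)
        return sig

    def _segment_times(self, n: int) -> np.ndarray:
        t = (self.sample_count + np.arange(n)) * self.dt
        return t

    def move_to(self, target_depth: float, speed: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Constant-speed move; returns (times, depths, samples)."""
        dist = abs(target_depth - self.depth)
        n = int(np.ceil(dist / speed / self.dt))
        if n == 0:
            self.depth = target_depth
            return (np.array([]),) * 3
        direction = np.sign(target_depth - self.depth)
        depths = self.depth + direction * speed * self.dt * np.arange(1, n + 1)
        depths = np.clip(depths, *sorted((self.depth, target_depth)))
        times = self._segment_times(n)
        samples = self._signal(depths, times)
        self.sample_count += n
        self.depth = float(depths[-1])
        return times, depths, samples

    def dwell(self, duration: float) -> tuple[np.ndarray, np.ndarray]:
        n = int(round(duration * self.motor.sampling_rate))
        depths = np.full(n, self.depth)
        times = self._segment_times(n)
        samples = self._signal(depths, times)
        self.sample_count += n
        return times, samples

    def pulses(self, depth: float | np.ndarray) -> np.ndarray:
        return np.rint(np.asarray(depth) * self.motor.pulses_per_mm).astype(int)

    # -- protocol building blocks -------------------------------------------

    def fast_descent_to_contact(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Descend fast, stop when the smoothed signal stays above the
        contact threshold for ``contact_sustain`` seconds."""
        prof, proto = self.profile, self.proto
        # generate past the nominal contact point, then truncate at detection
        overshoot = depth_for_pressure(prof, proto.contact_threshold + 4.0) + 0.2
        times, depths, samples = self.move_to(overshoot, self.motor.fast_speed)
        w = max(1, int(round(proto.contact_sustain / self.dt)))
        kernel = np.ones(w) / w
        trail = np.convolve(samples, kernel, mode="full")[: samples.size]
        above = np.flatnonzero(trail > proto.contact_threshold)
        above = above[above >= w - 1]
        stop = int(above[0]) if above.size else samples.size - 1
        # rewind instrument state to the detection sample
        self.sample_count -= samples.size - (stop + 1)
        self.depth = float(depths[stop])
        return times[: stop + 1], depths[: stop + 1], samples[: stop + 1]

    def servo_to_pressure(self, target: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Move at slow speed to the pulse position whose baseline best
        matches ``target`` (proportional approach collapsed to its fixed
        point; the motor quantizes depth to whole pulses)."""
        ideal = depth_for_pressure(self.profile, target)
        candidates = self.pulses(ideal) + np.array([-1, 0, 1])
        depths_c = candidates / self.motor.pulses_per_mm
        err = np.abs(baseline_pressure(self.profile, np.clip(depths_c, 0, None)) - target)
        hold_depth = float(depths_c[np.argmin(err)])
        return self.move_to(hold_depth, self.motor.slow_speed)

    def record_step(self, step_index: int, target: float) -> StepRecording:
        self.servo_to_pressure(target)
        t0 = self.time
        _, samples = self.dwell(self.proto.dwell)
        app = float(baseline_pressure(self.profile, self.depth))
        return StepRecording(
            step_index=step_index,
            target_pressure=float(target),
            app=app,
            motor_position=int(self.pulses(self.depth)),
            t0=t0,
            sampling_rate=self.motor.sampling_rate,
            samples=samples,
            within_tolerance=abs(app - target) <= self.motor.pressure_tolerance,
        )


def divide_pressure_range(p_start: float, p_end: float, n_steps: int = 5) -> np.ndarray:
    """Equally spaced step pressures with endpoints exactly at the range ends.

    E.g. a perceptible range of (25, 245) mmHg gives steps
    [25, 80, 135, 190, 245].
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if p_end <= p_start:
        raise ValueError(f"degenerate pressure range ({p_start}, {p_end})")
    return np.linspace(p_start, p_end, n_steps)


def run_descent_sweep(
    profile: SubjectProfile,
    motor: MotorConfig | None = None,
    proto: ProtocolConfig | None = None,
    seed: int = 0,
    _instrument: _Instrument | None = None,
) -> SweepTrace:
    """Fast approach + continuous slow descent, recording until the pulse is
    no longer perceived.

    Termination: once at least one qualifying beat peak has been seen, the
    sweep ends ``silence_window`` seconds after the last one; a hard stop at
    ``max_pressure`` protects the wrist.  Raises
    :class:`NoPulseDetectedError` if no beat qualifies before the stop.
    """
    motor = motor or MotorConfig()
    proto = proto or ProtocolConfig()
    ins = _instrument or _Instrument(profile, motor, proto, seed)

    ft, fd, fs = ins.fast_descent_to_contact()
    stop_depth = depth_for_pressure(profile, proto.max_pressure)
    st, sd, ss = ins.move_to(stop_depth, motor.slow_speed)

    prof_beats = signal_ops.beat_profile(
        ss, st, 0.5 * proto.min_peak_prominence, proto.min_beat_interval
    )
    qualifying = np.flatnonzero(prof_beats.amplitudes_smooth >= proto.min_peak_prominence)
    if qualifying.size == 0:
        raise NoPulseDetectedError(
            f"no pulse detected on subject {profile.subject_id} before "
            f"{proto.max_pressure} mmHg"
        )
    t_stop = prof_beats.peaks.times[qualifying[-1]] + proto.silence_window
    n_keep = int(np.searchsorted(st, t_stop, side="right"))
    n_keep = min(n_keep, ss.size)
    # rewind the instrument to the termination sample
    ins.sample_count -= ss.size - n_keep
    ins.depth = float(sd[n_keep - 1]) if n_keep else float(fd[-1])

    times = np.concatenate([ft, st[:n_keep]])
    depths = np.concatenate([fd, sd[:n_keep]])
    pressures = np.concatenate([fs, ss[:n_keep]])
    phases = np.concatenate(
        [np.full(ft.size, "fast-descent"), np.full(n_keep, "slow-sweep")]
    )
    return SweepTrace(times, pressures, ins.pulses(depths), phases)


def determine_pressure_range(
    sweep: SweepTrace,
    proto: ProtocolConfig | None = None,
    refine: bool = True,
) -> tuple[float, float]:
    """Subject-specific hold-down pressure range from the sweep.

    Candidate beat peaks are detected on the detrended slow sweep at half
    the perceptibility floor (``min_peak_prominence``); a beat qualifies
    when its (3-beat averaged) peak-to-foot amplitude reaches the floor.
    The first and last qualifying beats mark where the pulse is sensed
    first and last.  With ``refine=True`` (default) each endpoint is the
    hold-down pressure where the per-beat amplitude profile crosses the
    floor, linearly interpolated between the edge qualifying beat and its
    sub-threshold neighbour, which removes the up-to-one-beat quantization
    of the raw first/last-peak positions.
    """
    proto = proto or ProtocolConfig()
    mask = sweep.slow_mask
    t = sweep.times[mask]
    p = sweep.pressures[mask]
    if t.size < 3:
        raise ValueError("sweep too short to analyse")
    thr = proto.min_peak_prominence
    prof_beats = signal_ops.beat_profile(p, t, 0.5 * thr, proto.min_beat_interval)
    amps = prof_beats.amplitudes_smooth
    beat_bases = prof_beats.baselines
    qualifying = np.flatnonzero(amps >= thr)
    if qualifying.size == 0:
        raise NoPulseDetectedError("no beat peaks in sweep")
    if qualifying.size == 1:
        raise ValueError("degenerate pressure range: single beat peak in sweep")
    i0, i1 = int(qualifying[0]), int(qualifying[-1])
    p_start = float(beat_bases[i0])
    p_end = float(beat_bases[i1])
    if refine:
        p_start = _threshold_crossing(beat_bases, amps, i0, -1, thr)
        p_end = _threshold_crossing(beat_bases, amps, i1, +1, thr)
    if p_end <= p_start:
        raise ValueError(f"degenerate pressure range ({p_start}, {p_end})")
    return p_start, p_end


def _threshold_crossing(
    baselines: np.ndarray, amps: np.ndarray, k: int, outward: int, thr: float
) -> float:
    """Pressure where the per-beat amplitude profile crosses ``thr``.

    Interpolated between the edge qualifying beat ``k`` and its outward
    sub-threshold neighbour.  If that neighbour is missing (the beat fell
    below the candidate detection floor), the local slope through the two
    edge qualifying beats is extrapolated instead, clamped to one
    inter-beat pressure gap; with no usable neighbour at all the beat's own
    baseline is returned.
    """
    b0, a0 = baselines[k], amps[k]
    j = k + outward
    if 0 <= j < baselines.size and amps[j] < thr and abs(amps[j] - a0) > 1e-12:
        b1, a1 = baselines[j], amps[j]
        frac = (a0 - thr) / (a0 - a1)  # 0 at the edge beat, 1 at the neighbour
        return float(b0 + frac * (b1 - b0))
    i = k - outward  # inward neighbour for slope extrapolation
    if 0 <= i < baselines.size and abs(baselines[i] - b0) > 1e-9:
        slope = (a0 - amps[i]) / (b0 - baselines[i])
        if slope * outward < 0:  # amplitude falls toward the outside
            gap = abs(b0 - baselines[i])
            shift = float(np.clip((a0 - thr) / abs(slope), 0.0, gap))
            return float(b0 + outward * shift)
    return float(b0)


def run_existing_protocol(
    profile: SubjectProfile,
    motor: MotorConfig | None = None,
    proto: ProtocolConfig | None = None,
    seed: int = 0,
) -> AcquisitionResult:
    """Fixed-range protocol: descend and record at the manufacturer's five
    pressure steps (default 40..240 mmHg at 50-mmHg intervals).

    A step whose target exceeds the safety pressure is skipped and the
    result flagged ``partial`` rather than silently truncated.
    """
    motor = motor or MotorConfig()
    proto = proto or ProtocolConfig()
    ins = _Instrument(profile, motor, proto, seed)
    ins.fast_descent_to_contact()
    recordings: list[StepRecording] = []
    partial = False
    for i, target in enumerate(proto.fixed_step_pressures, start=1):
        if target > proto.max_pressure:
            partial = True
            continue
        recordings.append(ins.record_step(i, target))
    return AcquisitionResult(
        method="existing",
        subject_id=profile.subject_id,
        recordings=recordings,
        sweep=None,
        partial=partial,
        seed=seed,
    )


def run_proposed_protocol(
    profile: SubjectProfile,
    motor: MotorConfig | None = None,
    proto: ProtocolConfig | None = None,
    seed: int = 0,
) -> AcquisitionResult:
    """Adaptive protocol: descent sweep, subject-specific range, five equal
    steps measured on the way up (highest pressure first), re-indexed so
    step 1 is the lowest pressure."""
    motor = motor or MotorConfig()
    proto = proto or ProtocolConfig()
    ins = _Instrument(profile, motor, proto, seed)
    sweep = run_descent_sweep(profile, motor, proto, seed, _instrument=ins)
    p_start, p_end = determine_pressure_range(sweep, proto)
    steps = divide_pressure_range(p_start, p_end, proto.n_steps)
    recordings: list[StepRecording] = []
    for i in range(proto.n_steps, 0, -1):  # motor up: decreasing pressure
        recordings.append(ins.record_step(i, steps[i - 1]))
    recordings.sort(key=lambda r: r.step_index)
    return AcquisitionResult(
        method="proposed",
        subject_id=profile.subject_id,
        recordings=recordings,
        sweep=sweep,
        partial=False,
        seed=seed,
    )


def moving_distance(result: AcquisitionResult, motor: MotorConfig | None = None) -> float:
    """Step-motor travel (mm) between the first and last pressure steps —
    the instrument's proxy for pulse depth."""
    motor = motor or MotorConfig()
    return abs(result.step5_position - result.step1_position) / motor.pulses_per_mm
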