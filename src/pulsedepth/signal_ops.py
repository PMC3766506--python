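"""Waveform primitives: detrending, beat-peak detection, beat segmentation.

The continuous descent sweep superimposes the pulse on a rising pressure
ramp; `detrend_sweep` removes the ramp with a running median so that local
maxima of the residual are cardiac beats.  Peak detection uses topographic
prominence, with a greedy minimum-interval rule to keep one peak per beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps

__all__ = [
    "PeakList",
    "BeatProfile",
    "InsufficientBeatsError",
    "detrend_sweep",
    "smooth",
    "find_sweep_peaks",
    "beat_amplitudes",
    "beat_profile",
    "first_last_peaks",
    "segment_beats",
    "pulse_pressure",
]

#: prior on the expected beat period (s) used to size the detrend window;
#: covers a 40-150 bpm heart-rate prior.
EXPECTED_BEAT_PERIOD_S = 1.0
DETREND_WINDOW_PERIODS = 1.5


class InsufficientBeatsError(ValueError):
    """Raised when a recording contains too few beats to analyse."""


@dataclass
class PeakList:
    """Detected beat peaks on a (detrended) pressure series."""

    indices: np.ndarray          # sample indices, strictly increasing
    times: np.ndarray            # s
    amplitudes: np.ndarray       # detrended peak heights, mmHg
    prominences: np.ndarray      # topographic prominence, mmHg
    baselines: np.ndarray        # running-median hold-down pressure at peaks, mmHg

    def __len__(self) -> int:
        return int(self.indices.size)


def detrend_sweep(pressures: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Subtract a running median (window: 1.5 expected beat periods).

    Returns ``pressures - running_median``; the subtracted component is the
    ramp/baseline estimate and can be recovered as ``pressures - result``.
    The result is used to *locate* beats, not to measure them: on a steep
    ramp the median of a near-monotone window tracks the signal itself and
    attenuates the oscillation, so amplitudes are always re-read from the
    raw signal (see :func:`beat_amplitudes`).
    """
    p = np.asarray(pressures, dtype=float)
    t = np.asarray(times, dtype=float)
    if p.shape != t.shape:
        raise ValueError("pressures and times must have equal length")
    if p.size < 3:
        raise ValueError("series shorter than the detrend window")
    dt = float(t[1] - t[0])
    window = int(round(DETREND_WINDOW_PERIODS * EXPECTED_BEAT_PERIOD_S / dt))
    window = max(3, min(window | 1, p.size | 1))  # odd, within series
    if window > p.size:
        raise ValueError("series shorter than the detrend window")
    med = ndimage.median_filter(p, size=window, mode="nearest")
    return p - med


def smooth(series: np.ndarray, times: np.ndarray, window_s: float = 0.02) -> np.ndarray:
    """Moving-average pre-filter (default 20 ms) applied before peak detection.

    Suppresses sample-to-sample sensor noise without noticeably blunting
    beat peaks (systolic upstrokes last ~100 ms at physiological rates).
    """
    x = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if x.size < 2:
        return x.copy()
    dt = float(t[1] - t[0])
    w = max(1, int(round(window_s / dt)))
    if w == 1:
        return x.copy()
    kernel = np.ones(w) / w
    return np.convolve(np.pad(x, (w // 2, w - 1 - w // 2), mode="edge"), kernel, mode="valid")


def find_sweep_peaks(
    detrended: np.ndarray,
    times: np.ndarray,
    min_prominence: float,
    min_interval: float,
    baselines: np.ndarray | None = None,
) -> PeakList:
    """Local maxima with prominence >= ``min_prominence``, at least
    ``min_interval`` seconds apart.

    The interval rule is greedy: candidates are taken in order of
    decreasing height (earlier index wins an exact height tie) and a
    candidate is dropped if an already-accepted peak lies within
    ``min_interval``.  May return an empty list.
    """
    if min_prominence <= 0:
        raise ValueError("min_prominence must be > 0")
    x = np.asarray(detrended, dtype=float)
    t = np.asarray(times, dtype=float)
    cand, props = sps.find_peaks(x, prominence=min_prominence)
    if cand.size == 0:
        empty = np.array([], dtype=float)
        return PeakList(cand.astype(int), empty, empty, empty, empty)
    # greedy min-interval enforcement: higher peak wins, earlier index on ties
    order = np.lexsort((cand, -x[cand]))
    accepted: list[int] = []
    acc_times: list[float] = []
    for j in order:
        ti = t[cand[j]]
        if all(abs(ti - ta) >= min_interval for ta in acc_times):
            accepted.append(j)
            acc_times.append(ti)
    keep = np.sort(np.array([cand[j] for j in accepted], dtype=int))
    prom_map = dict(zip(cand.tolist(), props["prominences"].tolist()))
    prominences = np.array([prom_map[i] for i in keep], dtype=float)
    base = (
        np.asarray(baselines, dtype=float)[keep]
        if baselines is not None
        else np.full(keep.size, np.nan)
    )
    return PeakList(keep, t[keep], x[keep], prominences, base)


@dataclass
class BeatProfile:
    """Per-beat amplitude profile of a sweep or recording."""

    peaks: PeakList
    amplitudes: np.ndarray          # mmHg, raw per-beat peak-to-baseline
    amplitudes_smooth: np.ndarray   # mmHg, 3-beat running mean of the above
    baselines: np.ndarray           # mmHg, beat-free hold-down pressure at each beat

    def __len__(self) -> int:
        return int(self.amplitudes.size)


def beat_amplitudes(
    raw: np.ndarray, detrended: np.ndarray, times: np.ndarray, peaks: PeakList
) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat amplitude and hold-down baseline of each detected peak,
    measured on the raw signal against a linear baseline through the beat's
    surrounding diastolic feet.

    Feet are located on the (beat-shaped, ramp-free) detrended signal in the
    flat late-diastolic stretch just before each systolic upstroke — not at
    the global inter-beat minimum, which can land on the dicrotic tail.
    Foot values are window means (robust to noise); the peak value is the
    local maximum of the raw signal near the detected index.  Read off the
    raw signal this way, a linear pressure ramp cancels exactly and the
    detrending median's baseline bias never enters the amplitude.  Returns
    ``(amplitudes, baselines)``; the baseline is the foot-to-foot
    interpolated raw value under the peak, an essentially beat-free
    estimate of the hold-down pressure at the beat.
    """
    x = np.asarray(raw, dtype=float)
    d = np.asarray(detrended, dtype=float)
    t = np.asarray(times, dtype=float)
    n = len(peaks)
    if n == 0:
        return np.array([]), np.array([])
    idx = peaks.indices
    period = float(np.median(np.diff(idx))) if n > 1 else min(idx[0], x.size - 1 - idx[0])
    period = max(period, 3.0)
    w_lo = int(round(0.28 * period))    # pre-upstroke search window
    w_hi = int(round(0.05 * period))
    w_foot = max(2, int(round(0.04 * period)))
    feet = np.empty(n + 1, dtype=int)
    for k in range(n):
        lo = max(0, idx[k] - w_lo)
        hi = max(lo + 1, idx[k] - w_hi)
        feet[k] = lo + int(np.argmin(d[lo:hi]))
    # trailing foot: the diastole after the last beat's dicrotic wave
    lo = min(x.size - 2, idx[-1] + int(round(0.55 * period)))
    hi = min(x.size - 1, idx[-1] + int(round(0.90 * period)))
    feet[n] = lo + int(np.argmin(d[lo : hi + 1]))
    # read each foot as a window mean on its diastolic side, so the systolic
    # upstroke (pre-percussion feet) or dicrotic decay (trailing foot)
    # cannot leak into the baseline value; the mean estimates the baseline
    # at the *centre* of its window, and interpolating between those centre
    # times keeps the read exact on a linear pressure ramp
    foot_vals = np.empty(n + 1)
    foot_times = np.empty(n + 1)
    for k, f in enumerate(feet):
        if k < n:
            lo, hi = max(0, f - w_foot), f + 1
        else:
            lo, hi = f, min(x.size, f + w_foot + 1)
        foot_vals[k] = float(np.mean(x[lo:hi]))
        foot_times[k] = 0.5 * (t[lo] + t[hi - 1])
    w_pk = max(1, int(round(0.02 * period)))
    peak_vals = np.array(
        [float(np.max(x[max(0, i - w_pk) : min(x.size, i + w_pk + 1)])) for i in idx]
    )
    amps = np.empty(n)
    bases = np.empty(n)
    for k in range(n):
        t0f, t1f = foot_times[k], foot_times[k + 1]
        if t1f <= t0f:
            bases[k] = foot_vals[k]
        else:
            lam = (t[idx[k]] - t0f) / (t1f - t0f)
            bases[k] = (1.0 - lam) * foot_vals[k] + lam * foot_vals[k + 1]
        amps[k] = peak_vals[k] - bases[k]
    return amps, bases


def beat_profile(
    pressures: np.ndarray,
    times: np.ndarray,
    min_prominence: float,
    min_interval: float,
) -> BeatProfile:
    """Detect beats on a pressure sweep and estimate each beat's amplitude
    and hold-down baseline.

    Peaks are located on the smoothed detrended signal; values are then
    read from the smoothed raw signal through small windows (local max at
    the peak, window mean at the feet), which keeps the noise-selection
    bias of reading at an argmax/argmin index to a fraction of the sample
    noise.  The 3-beat running mean of the amplitude profile is also
    provided: beat qualification against a perceptibility floor is far more
    stable on it.
    """
    p = np.asarray(pressures, dtype=float)
    t = np.asarray(times, dtype=float)
    det = detrend_sweep(p, t)
    sm_loc = smooth(det, t, window_s=0.02)
    sm_read = smooth(p, t, window_s=0.02)
    peaks = find_sweep_peaks(sm_loc, t, min_prominence, min_interval, baselines=p - det)
    amps, bases = beat_amplitudes(sm_read, sm_loc, t, peaks)
    if amps.size >= 3:
        kernel = np.ones(3) / 3.0
        # linear-extrapolation padding keeps the running mean unbiased at the
        # profile edges, where the envelope is locally linear
        padded = np.concatenate(
            [[2 * amps[0] - amps[1]], amps, [2 * amps[-1] - amps[-2]]]
        )
        amps_smooth = np.convolve(padded, kernel, mode="valid")
    else:
        amps_smooth = amps.copy()
    return BeatProfile(peaks, amps, amps_smooth, bases)


def first_last_peaks(peaks: PeakList) -> tuple[int, int, bool]:
    """Indices (into the peak list) of the first and last peaks.

    Returns ``(0, len-1, degenerate)`` where ``degenerate`` flags the
    single-peak case in which both endpoints coincide.
    """
    if len(peaks) == 0:
        raise ValueError("empty peak list")
    return 0, len(peaks) - 1, len(peaks) == 1


def segment_beats(
    samples: np.ndarray,
    times: np.ndarray,
    min_beat_interval: float = 0.33,
    min_prominence: float = 1.0,
) -> list[tuple[int, int]]:
    """Split a constant-pressure recording into (foot index, peak index) beats.

    Peaks are detected on the detrended record; the foot of each beat is the
    sample minimum between the previous peak and it.  The partial first and
    last beats (no preceding foot / truncated decay) are dropped.
    """
    x = np.asarray(samples, dtype=float)
    t = np.asarray(times, dtype=float)
    det = detrend_sweep(x, t)
    sm = smooth(det, t)
    peaks = find_sweep_peaks(sm, t, min_prominence, min_beat_interval)
    if len(peaks) < 3:
        raise InsufficientBeatsError(
            f"insufficient beats: found {len(peaks)}, need >= 3"
        )
    beats: list[tuple[int, int]] = []
    for k in range(1, len(peaks)):
        lo, hi = peaks.indices[k - 1], peaks.indices[k]
        foot = lo + int(np.argmin(x[lo:hi]))
        beats.append((foot, int(peaks.indices[k])))
    return beats


def pulse_pressure(
    samples: np.ndarray,
    times: np.ndarray,
    min_beat_interval: float = 0.33,
    min_prominence: float = 1.0,
) -> float:
    """Pulse pressure of a recording: mean peak-minus-foot amplitude over
    complete beats.

    Per-beat amplitudes come from :func:`beat_amplitudes` (peak against the
    foot-to-foot interpolated baseline), so the estimate resists slow drift
    — adding a constant to the recording leaves it unchanged — and the
    windowed value reads keep sensor noise from biasing it.
    """
    x = np.asarray(samples, dtype=float)
    prof = beat_profile(x, times, min_prominence, min_beat_interval)
    if len(prof) < 3:
        raise InsufficientBeatsError(f"insufficient beats: found {len(prof)}, need >= 3")
    amps = prof.amplitudes
    if amps.size >= 5:  # drop the possibly partial first and last beats
        amps = amps[1:-1]
    return float(np.mean(amps))
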