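"""Synthetic radial-pulse subject model.

A :class:`SubjectProfile` describes one wrist as seen by a single-channel
tonometric pressure sensor: how hold-down (baseline) pressure grows with
sensor depth (tissue compliance), and how the pulsatile amplitude varies
with hold-down pressure (the P-H envelope).  Given any motor-depth
trajectory the model produces the sensor pressure signal

    signal(t) = baseline(depth(t)) + envelope(baseline) * beat(phase(t)) + noise,

which is what the acquisition protocols consume.  Everything is
deterministic given a seed.

The P-H envelope is a Gaussian bump: amplitude ``a_max`` at ``p_peak``,
falling to the detectability floor ``a_thresh`` exactly at ``p_first`` and
``p_last``.  Subcutaneous-tissue thickness is emulated through BMI: heavier
subjects get a deeper contact point and an envelope shifted toward higher
hold-down pressures (a "sinking-prone" wrist).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "BeatShape",
    "SubjectProfile",
    "BMICoupling",
    "make_cohort",
    "envelope_amplitude",
    "baseline_pressure",
    "depth_for_pressure",
    "sensor_signal",
    "save_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class BeatShape:
    """Unit-amplitude periodic pulse waveform on phase [0, 1).

    Two wrapped Gaussian bumps (percussion + dicrotic wave), shifted and
    scaled so the minimum over one period is exactly 0 and the maximum
    exactly 1.
    """

    percussion_center: float = 0.13
    percussion_width: float = 0.045
    dicrotic_center: float = 0.40
    dicrotic_width: float = 0.06
    dicrotic_weight: float = 0.30
    _lo: float = field(init=False, repr=False, default=0.0)
    _hi: float = field(init=False, repr=False, default=1.0)

    def __post_init__(self) -> None:
        grid = np.linspace(0.0, 1.0, 4001, endpoint=False)
        raw = self._raw(grid)
        object.__setattr__(self, "_lo", float(raw.min()))
        object.__setattr__(self, "_hi", float(raw.max()))

    def _raw(self, phase: np.ndarray) -> np.ndarray:
        ph = np.asarray(phase, dtype=float) % 1.0
        out = np.zeros_like(ph)
        # wrap each bump over neighbouring periods so the waveform is periodic
        for k in (-1.0, 0.0, 1.0):
            out += np.exp(-0.5 * ((ph - self.percussion_center + k) / self.percussion_width) ** 2)
            out += self.dicrotic_weight * np.exp(
                -0.5 * ((ph - self.dicrotic_center + k) / self.dicrotic_width) ** 2
            )
        return out

    def __call__(self, phase: np.ndarray | float) -> np.ndarray:
        raw = self._raw(np.atleast_1d(np.asarray(phase, dtype=float)))
        return (raw - self._lo) / (self._hi - self._lo)


@dataclass(frozen=True)
class BMICoupling:
    """Linear maps from BMI to contact depth and envelope-peak offset.

    ``contact_depth = contact_base + contact_per_bmi * (bmi - 22)`` and the
    envelope peak is pushed ``peak_shift_per_bmi`` mmHg toward the deep end
    per BMI unit above 25, mirroring the thicker subcutaneous layer of
    overweight wrists.
    """

    contact_base_mm: float = 1.5
    contact_per_bmi_mm: float = 0.08
    peak_shift_per_bmi_mmhg: float = 1.5
    overweight_cutoff: float = 25.0


@dataclass
class SubjectProfile:
    """Generative parameters of one simulated wrist."""

    subject_id: str
    heart_rate: float = 72.0        # beats/min
    p_first: float = 25.0           # mmHg, pulse first detectable
    p_peak: float = 135.0           # mmHg, envelope maximum
    p_last: float = 245.0           # mmHg, pulse vanishes (occlusion)
    a_max: float = 10.0             # mmHg, peak pulsatile amplitude
    a_thresh: float = 2.0           # mmHg, amplitude at p_first / p_last
    contact_depth: float = 1.5      # mm of motor travel before skin contact
    stiffness: float = 50.0         # mmHg/mm at unit indentation
    gamma: float = 1.2              # compliance nonlinearity exponent
    noise_sd: float = 0.0           # mmHg, i.i.d. Gaussian sensor noise
    bmi: float = 22.0               # kg/m^2

    def __post_init__(self) -> None:
        if not (self.p_first < self.p_peak < self.p_last):
            raise ValueError(
                f"require p_first < p_peak < p_last, got "
                f"({self.p_first}, {self.p_peak}, {self.p_last})"
            )
        if not (0.0 < self.a_thresh < self.a_max):
            raise ValueError("require 0 < a_thresh < a_max")
        if not (30.0 <= self.heart_rate <= 180.0):
            raise ValueError("heart_rate outside 30-180 beats/min")
        if self.stiffness <= 0 or self.noise_sd < 0 or self.contact_depth < 0:
            raise ValueError("stiffness must be > 0; noise_sd, contact_depth >= 0")
        L = self.p_peak - self.p_first
        R = self.p_last - self.p_peak
        lim = math.sqrt(2.0) - 1.0
        if not (lim < L / R < 1.0 / lim):
            raise ValueError(
                f"envelope too asymmetric: (p_peak-p_first)/(p_last-p_peak) = "
                f"{L / R:.3f} must lie in ({lim:.3f}, {1 / lim:.3f}) for the "
                "warped-Gaussian envelope to stay unimodal"
            )

    @property
    def envelope_sigma(self) -> tuple[float, float]:
        """Equivalent per-side Gaussian widths (below-peak, above-peak).

        In the symmetric case (p_peak at the range midpoint) both equal the
        sigma of the plain Gaussian bump through (p_first, a_thresh),
        (p_peak, a_max), (p_last, a_thresh).
        """
        k = math.sqrt(2.0 * math.log(self.a_max / self.a_thresh))
        return (self.p_peak - self.p_first) / k, (self.p_last - self.p_peak) / k

    @property
    def _warp_coeffs(self) -> tuple[float, float, float]:
        """(a, b, k) of the monotone warp z(p) = a*(p-p_peak) + b*(p-p_peak)^2
        with z(p_first) = -k, z(p_peak) = 0, z(p_last) = +k."""
        k = math.sqrt(2.0 * math.log(self.a_max / self.a_thresh))
        L = self.p_peak - self.p_first
        R = self.p_last - self.p_peak
        a = k * (L * L + R * R) / (L * R * (L + R))
        b = k * (L - R) / (L * R * (L + R))
        return a, b, k

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectProfile":
        return cls(**d)


def envelope_amplitude(profile: SubjectProfile, p: np.ndarray | float) -> np.ndarray | float:
    """Pulsatile amplitude (mmHg) at hold-down pressure ``p``.

    A Gaussian bump in a smoothly warped pressure coordinate:
    ``a_max * exp(-z(p)^2 / 2)`` with the monotone quadratic warp ``z``
    pinned so the amplitude is exactly ``a_max`` at ``p_peak`` and exactly
    ``a_thresh`` at ``p_first`` and ``p_last``.  When ``p_peak`` is the
    range midpoint this reduces to the plain symmetric Gaussian
    ``a_max * exp(-(p - p_peak)^2 / (2 sigma^2))``; off-centre peaks skew
    the bump smoothly instead of splitting it.  Values below ``a_thresh``
    are returned as-is — whether a beat is *detectable* is decided by the
    peak detector downstream, not here.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("hold-down pressure must be >= 0")
    a, b, _ = profile._warp_coeffs
    dp = p_arr - profile.p_peak
    z = a * dp + b * dp * dp
    out = profile.a_max * np.exp(-0.5 * z * z)
    # contact taper: an unloaded sensor transmits no pulse; negligible
    # (<1e-10 relative) anywhere at or beyond p_first
    out = out * -np.expm1(-p_arr / 1.0)
    return float(out) if np.isscalar(p) else out


def baseline_pressure(profile: SubjectProfile, depth: np.ndarray | float) -> np.ndarray | float:
    """Static hold-down pressure (mmHg) at motor depth (mm).

    Zero until the sensor touches skin at ``contact_depth``; a power-law
    ``stiffness * (depth - contact_depth)**gamma`` beyond it.
    """
    d = np.asarray(depth, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be >= 0")
    x = np.clip(d - profile.contact_depth, 0.0, None)
    out = profile.stiffness * x**profile.gamma
    return float(out) if np.isscalar(depth) else out


def depth_for_pressure(profile: SubjectProfile, p: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`baseline_pressure` above contact (p=0 -> contact depth)."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0):
        raise ValueError("pressure must be >= 0")
    out = profile.contact_depth + (p_arr / profile.stiffness) ** (1.0 / profile.gamma)
    return float(out) if np.isscalar(p) else out


def sensor_signal(
    profile: SubjectProfile,
    depth_trajectory: np.ndarray,
    times: np.ndarray,
    seed: int,
    beat: BeatShape | None = None,
    phase_offset: float = 0.0,
) -> np.ndarray:
    """Sensor pressure samples (mmHg) along a motor-depth trajectory.

    ``times`` must be uniformly spaced and strictly increasing; the cardiac
    phase is ``phase_offset + heart_rate/60 * t`` so a caller stitching
    consecutive segments keeps beats continuous by passing absolute times.
    """
    depth = np.asarray(depth_trajectory, dtype=float)
    t = np.asarray(times, dtype=float)
    if depth.shape != t.shape:
        raise ValueError("depth_trajectory and times must have equal length")
    if t.size > 1:
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("times must be strictly increasing and uniform")
    beat = beat or BeatShape()
    base = baseline_pressure(profile, depth)
    amp = envelope_amplitude(profile, base)
    phase = phase_offset + profile.heart_rate / 60.0 * t
    sig = base + amp * beat(phase)
    if profile.noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, profile.noise_sd, size=sig.shape)
    return sig


def make_cohort(
    n: int,
    seed: int,
    bmi_range: tuple[float, float] = (18.5, 31.0),
    coupling: BMICoupling | None = None,
    noise_sd: float = 0.0,
) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles, deterministic given ``seed``.

    BMI is uniform over ``bmi_range``.  Subjects at or above the overweight
    cutoff (25 kg/m^2) receive an envelope peak above the midpoint of their
    pressure range — the deep, "sinking-prone" wrist that motivates the
    adaptive protocol — via :class:`BMICoupling`.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    lo, hi = bmi_range
    if lo > hi:
        raise ValueError(f"inverted bmi_range {bmi_range}")
    coupling = coupling or BMICoupling()
    rng = np.random.default_rng(seed)
    cohort: list[SubjectProfile] = []
    for i in range(n):
        bmi = float(rng.uniform(lo, hi))
        heart_rate = float(rng.uniform(60.0, 90.0))
        p_first = float(rng.uniform(15.0, 35.0))
        p_last = float(rng.uniform(235.0, 270.0))
        mid = 0.5 * (p_first + p_last)
        if bmi >= coupling.overweight_cutoff:
            # thicker subcutaneous tissue: envelope peak above the midpoint
            shift = coupling.peak_shift_per_bmi_mmhg * (bmi - coupling.overweight_cutoff)
            p_peak = mid + min(6.0 + shift, 30.0)
        else:
            p_peak = mid + float(rng.uniform(-30.0, 25.0))
        contact = coupling.contact_base_mm + coupling.contact_per_bmi_mm * (bmi - 22.0)
        cohort.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                heart_rate=heart_rate,
                p_first=p_first,
                p_peak=p_peak,
                p_last=p_last,
                a_max=float(rng.uniform(8.0, 14.0)),
                a_thresh=2.0,
                contact_depth=max(contact, 0.2),
                stiffness=float(rng.uniform(40.0, 62.0)),
                gamma=1.2,
                noise_sd=noise_sd,
                bmi=bmi,
            )
        )
    return cohort


def save_cohort(cohort: list[SubjectProfile], path: str | Path, seed: int | None = None) -> None:
    payload = {"seed": seed, "subjects": [p.to_dict() for p in cohort]}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_cohort(path: str | Path) -> list[SubjectProfile]:
    payload = json.loads(Path(path).read_text())
    return [SubjectProfile.from_dict(d) for d in payload["subjects"]]
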