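# Methods

This note documents the models, algorithms and numerical choices behind
`pulsedepth`: a simulated pulse-diagnosis instrument (step motor + single
pressure channel) pressing on a generative wrist model, running a
fixed-range and an adaptive pulse-wave acquisition protocol, and the
floating/sinking (CFS) analysis of the resulting P-H curves.

## The generative wrist model

A `SubjectProfile` is fully described by tissue compliance, a P-H
envelope, a beat shape and sensor noise. The sensor signal along any
motor-depth trajectory `d(t)` is

```
s(t) = B(d(t)) + A(B(d(t))) · beat(f_hr·t) + ε(t),    ε ~ N(0, noise_sd²)
```

**Compliance.** Hold-down (baseline) pressure is zero until the sensor
meets the skin at `contact_depth` (mm) and follows a power law beyond it:
`B(d) = stiffness · (d − contact_depth)^γ`, with defaults
`stiffness = 40–62 mmHg/mm` and `γ = 1.2`. These defaults put the
step1→step5 motor travel of a 200-mmHg fixed range at 2–4 mm, the scale a
real instrument reports. The inverse `depth_for_pressure` is closed-form.

**P-H envelope.** Pulse amplitude versus hold-down pressure is a Gaussian
bump in a smoothly warped pressure coordinate:

```
A(p) = a_max · exp(−z(p)²/2),   z(p) = a·(p − p_peak) + b·(p − p_peak)²
```

with the monotone quadratic warp pinned so that `A(p_peak) = a_max` and
`A(p_first) = A(p_last) = a_thresh` exactly (`a_thresh` is the
perceptibility floor — the amplitude at which the instrument first/last
senses the pulse). When `p_peak` is the midpoint of `(p_first, p_last)`
the warp is linear and the envelope is the plain symmetric Gaussian. This
family was chosen over the two obvious alternatives:

* a single-σ Gaussian cannot satisfy both boundary conditions unless the
  peak is centred;
* a split (per-side σ) Gaussian satisfies them but has a curvature kink at
  the peak that biases the 5-knot P-H spline's argmax by up to ~9 mmHg
  even with exact knot values.

The warped family is C¹-smooth, unimodal, and keeps the intrinsic
spline-argmax bias below ~4 mmHg for peak offsets up to ±40 mmHg from the
range midpoint. Its validity domain requires the side-width ratio
`(p_peak−p_first)/(p_last−p_peak)` to lie in `(√2−1, √2+1)`; profiles
outside it are rejected at construction. A contact taper
`(1 − e^{−p/1 mmHg})` zeroes the pulse for an unloaded sensor; it is
numerically invisible (<10⁻¹⁰ relative) anywhere at or beyond `p_first`.

**Beat shape.** A unit-amplitude periodic waveform of two wrapped Gaussian
bumps — percussion wave (phase 0.13, width 0.045) and dicrotic wave
(phase 0.40, width 0.06, weight 0.3) — rescaled so its minimum is exactly
0 and maximum exactly 1 per period. The systolic complex occupies roughly
the physiological third of the cycle; waveform morphology beyond
"percussion + dicrotic" is out of scope.

**Cohort generator.** `make_cohort(n, seed)` draws heart rate 60–90 bpm,
`p_first` 15–35 mmHg, `p_last` 235–270 mmHg, `a_max` 8–14 mmHg
(`a_thresh` fixed at 2 mmHg), stiffness 40–62 mmHg/mm, and BMI uniform on
a configurable range. BMI couples linearly into contact depth and into
the envelope peak: subjects at or above 25 kg/m² get `p_peak` pushed
above their range midpoint (deep, sinking-prone wrists — the thicker
subcutaneous layer), by `6 + 1.5·(BMI−25)` mmHg, capped at +30. Normal
subjects draw peak offsets uniformly in (−30, +25) mmHg about the
midpoint. Offsets are kept within ±30 mmHg deliberately: the five-step
P-H spline cannot localize the maximum of a strongly skewed envelope to
better than ~half the inter-knot bias, so stronger skews would make `X`
an estimate of spline geometry rather than of the wrist (see
*Limitations*). All draws are `numpy.random.default_rng(seed)`;
identical seeds give bit-identical cohorts, signals and protocol runs.

## Protocol engines

Motor speeds follow the instrument's fast/slow convention — 1.563 mm/s
approach, 0.125 mm/s working speed (the source material prints "m/s",
which would cross the whole working range in milliseconds; mm/s is the
only physically consistent reading). The motor is quantized to
5 µm/pulse (200 pulses/mm, configurable); sampling is 500 Hz; each step
dwells 10 s.

**Contact detection** ends the fast approach when the 20-ms trailing mean
of the signal stays above 5 mmHg.

**Fixed-range protocol**: slow descent servos to each of
40/90/140/190/240 mmHg in turn (proportional approach collapsed to its
fixed point, depth quantized to whole pulses — per-pulse pressure
resolution ≤0.5 mmHg, well inside the ±2 mmHg tolerance), records 10 s,
and stores the actual applied pressure (APP = mean baseline during the
dwell). A step whose target exceeds the 300-mmHg safety limit is skipped
and the result flagged partial.

**Adaptive protocol**: after contact the sensor descends at 0.125 mm/s
recording continuously. The sweep ends `silence_window = 2 s` after the
last qualifying beat (or at the safety limit); the emulation generates
the full descent once, computes the beat profile, and truncates — 
equivalent to the causal rule because inter-beat gaps inside the
detection band are well below 2 s. The recovered range is divided into
`n_steps = 5` equal pressures and measured during ascent (highest
pressure first), then re-indexed so step 1 is the lightest.

## Signal processing

**Detrending** subtracts a running median (window 1.5× the expected 1-s
beat period). One property matters and is easy to miss: on a *steep* ramp
(sweep rate ≈ 6–8 mmHg/s) the window is nearly monotone, and the median
of a near-monotone window is its central sample — the filter then tracks
the signal itself and attenuates the oscillation. The detrended trace is
therefore used only to *locate* beats and feet; no amplitude is ever read
from it.

**Peak detection** (`find_sweep_peaks`) takes local maxima with
topographic prominence ≥ threshold and greedily enforces a minimum
inter-peak interval (higher peak wins; earlier index on exact ties). It
performs no smoothing internally and is verified against a brute-force
O(n·w) oracle. The acquisition pipeline pre-smooths with a 20-ms moving
average (at 500 Hz, raw Gaussian noise would otherwise produce spurious
prominence peaks). The default `min_beat_interval = 0.33 s` admits heart
rates to 180 bpm and, at resting rates, also suppresses the dicrotic peak
(0.2–0.3 s after percussion) through the greedy rule.

**Per-beat amplitude and baseline** (`beat_amplitudes`): for each
detected peak, the two surrounding diastolic feet are located on the
detrended trace — in the flat pre-upstroke stretch, not at the global
inter-beat minimum, which can land on the dicrotic tail — and the beat is
measured on the *raw* (lightly smoothed) signal: peak value as a
small-window local max, foot values as one-sided window means on their
diastolic side, and the baseline under the peak as the foot-to-foot
interpolation using each window's centre time (exact on a linear ramp).
Reading values through small windows rather than at argmax/argmin indices
bounds the noise-selection bias to a fraction of the sample noise.

**Pressure-range recovery** (`determine_pressure_range`): candidate beats
are detected at half the perceptibility floor
(`min_peak_prominence = 2 mmHg`, equal by design to the simulator's
`a_thresh`); a beat qualifies when the 3-beat running mean of its
amplitude profile (linear-extrapolation edge padding) reaches the floor.
Each endpoint is the interpolated floor-crossing of the amplitude profile
between the edge qualifying beat and its sub-threshold neighbour; if that
neighbour fell below the candidate floor the local slope through the two
edge qualifying beats is extrapolated instead (clamped to one inter-beat
gap). This removes the up-to-one-beat quantization (≈5–10 mmHg of ramp
travel per beat) of the naive "first/last detected peak" rule; that
literal rule remains available as `refine=False`. Measured on noiseless
40-subject cohorts the recovered endpoints are within 1.7 mmHg of the
generative `(p_first, p_last)`; 0.5-mmHg sensor noise moves them by less
than ~5 mmHg.

**Pulse pressure** of a step recording is the mean per-beat amplitude
over complete beats (the possibly clipped first and last beats are
dropped). It is translation-invariant and scale-equivariant, and
recovers the generative envelope at the five APPs to within 2%
noiselessly. A recording with no detectable beats — e.g. a fixed-range
step outside the subject's perceptible range — contributes a pulse
pressure of 0 in the analysis pipeline (the instrument feels nothing
there); calling the estimator directly on such a recording raises.

## P-H analysis and CFS

The P-H curve is a natural cubic spline (zero second derivative at the
ends) through the five (APP, pulse-pressure) points; `X` is its argmax on
a 0.1-mmHg grid over `[X_min, X_max]`, ties resolving to the lowest
pressure. `CFS = 10(X − X_min)/(X_max − X_min)` with `X_min`/`X_max`
taken from the measured APPs (they, not the commanded targets, are what
the instrument reports); floating if `CFS < 5`, sinking if `CFS ≥ 5`
(the boundary side is forced by the reference table: 4.998414 is printed
Floating, 5.031552 Sinking). The threshold rule reproduces all 40
printed floating/sinking calls. `newCFS = (Y₁+Y₂)/2 − (Y₄+Y₅)/2` is
reported in mmHg, positive for floating-like curves, and is not used for
classification (a single palpation position does not license the call).

## Cohort statistics

Mean and SD use the n−1 denominator (the packaged table's printed SDs
confirm this: the population-SD alternative reproduces neither 0.994 nor
1.183). The paired t-test computes `t = d̄/(s_d/√n)` with a two-sided
p-value through the regularized incomplete beta function; Pearson r is
the sample product-moment form. All three kernels agree with independent
high-precision references to ≤10⁻⁹ in the test suite. Spearman rank
correlation is exposed alongside Pearson because the two protocols' CFS
values need not be linearly related. For identical paired samples the
t-test returns (t=0, p=1) rather than erroring; a constant non-zero
difference (zero variance, non-zero mean) errors.

The packaged 20-subject reference table ships as CSV with a SHA-256
checksum verified at load. Two of its newCFS digit runs are ambiguous at
the 4th decimal in the available source and one row header is corrupted;
the transcription notes in `cohort_stats` document the parse. Those
columns feed no summary statistic. The printed SD 0.994 of the
fixed-method moving distance is a truncation of the exact 0.99455;
comparisons accept one unit in the last printed digit.

## What the simulation does and does not establish

The generator emulates the features the protocols interact with — a
unimodal perceptibility envelope with subject-specific range and depth, a
monotone compliance linking motor travel to pressure, BMI-coupled depth,
periodic two-bump beats, i.i.d. Gaussian sensor noise. It does not
emulate motion artifacts, respiratory or vasomotor baseline drift, beat-
to-beat amplitude variability, arrhythmia, sensor hysteresis, motor
backlash, or the six-sensor array geometry and temperature compensation
of the real instrument (one ideal pressure channel stands for all of it).
Passing tests therefore demonstrate that the protocol logic and analysis
chain are correct and self-consistent — sweep endpoints recover the
generative range, the adaptive method travels farther whenever the true
range is wider than the fixed window, symmetric envelopes score CFS 5 —
not that the instrument would achieve those accuracies on real wrists.
Subject-level envelope parameters are free simulator choices; no
quantitative P-H data per subject exists to validate them against, which
is why the reference study's per-subject numbers enter only through the
packaged printed table.

## Known limitations

* `X` localization degrades for strongly skewed envelopes (intrinsic to a
  5-knot spline; offsets beyond ~±40 mmHg from the range midpoint are
  outside the default generator for this reason, and the profile
  validator rejects side-width ratios beyond `(√2−1, √2+1)` outright).
* The running-median detrender attenuates the oscillation on steep ramps;
  all quantitative reads bypass it (see above), but third parties using
  `detrend_sweep` output as an amplitude estimate should not.
* The sweep-termination rule (2 s silence) and the perceptibility floor
  (2 mmHg) are design constants of this implementation; the source
  material specifies neither.
* The fixed protocol can measure steps outside a subject's perceptible
  range; their pulse pressure is reported as 0 rather than an error,
  which makes the edge knots of the P-H spline exact zeros instead of
  small noisy values.
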