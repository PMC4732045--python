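# Methods

## Model and conventions

The global frame has X vertical (gravity `[9.81, 0, 0]ᵀ` m/s², up
positive), Y forward and Z mediolateral; sagittal-plane rotation ("pitch")
is therefore rotation about Z, and "roll" is rotation about Y. All
orientation matrices map sensor-frame vectors into the global frame.

The initial transformation matrix is assembled as
`G_R0 = R_y(θ_y0) · R_z(θ_z0)` with the passive-layout factors
`R_z = [[c, s, 0], [−s, c, 0], [0, 0, 1]]` and
`R_y = [[c, 0, s], [0, 1, 0], [−s, 0, c]]`. This composition order is not
a free choice: it is the unique order for which the tilt-angle formulas
`θ_z0 = arctan2(G_y, G_x)`, `θ_y0 = arctan2(G_z, √(G_x²+G_y²))` recover
the assembly angles exactly and `G_R0 · SG = [9.81, 0, 0]ᵀ` holds for any
stationary gravity reading `SG`. The gravity-alignment identity is treated
as the operative definition of the sign convention and is asserted in the
tests. The heading (yaw about vertical) is unobservable from gravity and
fixed at zero; only the vertical acceleration component is integrated, so
an erroneous constant heading cannot bias the clearance.

The strapdown recursion is the faithful first-order additive update
`R_i = R_{i−1} + R_{i−1}[Δt·ω_i]_×` with no re-orthonormalization. Its two
error modes are quantified rather than patched: the orientation deviates
from a matrix-exponential oracle by well under 0.5° over a 10 s walk at
200 Hz with rates up to 8 rad/s (per-step angle error `(ωΔt)³/3` largely
cancels over zero-net swings), and the determinant inflates as
`exp(Σ ω²Δt²)` (about 1.9 after 10 s at 8 rad/s peak), which leaks a
slowly growing scale onto gravity. Because that leak is almost constant
within a stride, the linear velocity ramp removes most of it; the residue
is the dominant term in the pipeline's error floor (see below). An
`"exact"` Rodrigues mode exists solely as the oracle in tests.

## Calibration

Model `A = S(Am − B)`. The norm-only objective cannot distinguish `S` from
`Q·S` for any rotation `Q`, so `S` is parameterized symmetric (6
parameters; a diagonal 3-parameter mode is available) plus the 3-vector
`B`. A damped Gauss–Newton iteration on the residuals
`r_k = ‖S(Am_k − B)‖ − g` starts from `S = I, B = 0` with analytic
Jacobian; the damping parameter guarantees a monotone cost over accepted
steps. Convergence is declared at gradient infinity-norm below 1e-10, or
when no damped step can reduce the cost further and the gradient is below
1e-6 — for noisy readings the achievable gradient floor is
`O(√(ε_mach · cost))`, around 1e-8 for a realistic static set, so
demanding 1e-10 there would mislabel a machine-precision minimum as
failure. A stall with a large gradient still raises, as do N ≤ 20
orientations or a degenerate (coplanar) orientation set. Static readings
are per-orientation means over ≥ 1 s to suppress noise.

## Filtering

Gyro: first-order Butterworth band-pass 0.001–5 Hz, realized as identity
minus the complementary first-order 0.001 Hz low-pass (exact for first
order) cascaded with a 5 Hz low-pass. Accelerometer: first-order 10 Hz
low-pass only — the constant component is the gravity projection and must
survive. Both are applied forward–backward (zero-phase) by default because
processing is offline and a causal first-order filter's group delay would
shift the detected gait events; a causal mode exists for comparison. The
0.001 Hz trend filter has a pole within 1e-7 of the unit circle and a
transient far longer than any trial, so it uses Gustafsson initial
conditions (minimum edge transient) rather than padding; with default
padding the transient is larger than the signal. Note that first-order
filters roll off gently: the 5 Hz gyro low-pass attenuates real swing
harmonics at 2–4 Hz by several percent, which is part of the method's
error floor, not an implementation artifact.

## Event detection

Stationary lead: longest prefix where the mean-centred rate magnitude
stays below 0.05 rad/s (≥ 0.5 s required), with the coarse threshold
crossing backtracked to the still-phase noise floor — a C²-smooth motion
onset crosses any fixed threshold late, so without refinement the boundary
would land ~5–10 samples into the movement at 200 Hz.

Foot-flat detection thresholds on |gyro_z| with hysteresis (enter below
0.3 rad/s, exit above 0.5 rad/s), keeps runs of at least 0.1 s, and trims
each run's smooth tails to a near-zero floor: `max(0.01 rad/s, 1.1 × the
98th percentile of the run core)` — the percentile term keeps correlated
filtered-noise humps from dragging boundaries, while clean signals trim to
the fixed epsilon (boundaries within ±5 samples of generator truth). If
trimming would leave less than the minimum flat duration but the
below-threshold run is at least twice that duration — the signature of a
real but filter-smeared short flat, as in fast gait — the flattest
admissible window of the run is kept instead; brief mid-swing rate
reversals fail both gates. Strides span flat-end to flat-end with
plausibility gates of 0.3–3 s. Detection uses the magnitude, so it is
invariant to the left/right mirror of the rate sign.

The first heel-off is refined from the gravity-free acceleration norm: the
stance foot can rotate about the heel before actually translating, so the
boundary moves to the first sustained (3-sample) exceedance of 0.5 m/s²,
searched from just before the gyro-detected boundary onward (translation
never leads rotation by much; restricting the search keeps noise bursts in
the long stationary lead from faking an onset). Agreement within 25 ms is
left unchanged.

## Integration and correction

Per stride (local time `t` from the stride start, duration `T`):
trapezoidal integration of the vertical gravity-free acceleration from
zero velocity, then `V_corr(t) = V(t) − (V(T)/T)t`; trapezoidal
integration of `V_corr` from zero displacement, then
`D_corr(t) = D(t) − (D(T)/T)t`. The corrections are applied in exactly
this order. Both terminal values are zero to machine precision by
construction, and a constant acceleration offset within a stride is
cancelled exactly by the velocity ramp. Clearance is clamped to zero on
detected foot-flat samples only — negative mid-swing excursions are
reported as computed, not clipped, so they remain visible as diagnostics.
Samples outside any stride (e.g. the stationary lead) are zero.

## Synthetic gait generator

The generator emulates the validation conditions: a ≥ 1 s stationary lead
followed by n strides of swing + foot-flat. Defaults (fixed as the study
conditions): normal — 5 strides × 1.1 s, foot-flat fraction 0.35, peak
clearance 0.20 m, peak sagittal rate 4.5 rad/s, speed 1.0 m/s; fast —
0.85 s strides at 1.7 m/s, 6.5 rad/s; obstacle — per-stride peaks up to
0.45 m (obstacle clearance being roughly three times normal). Walking
speeds match published averages for these conditions; the pitch-rate peak
corresponds to a ~45° sagittal foot excursion, typical of swing.

The swing bump is `h(s) = P sin⁴(πs)` (C² at the flat boundaries, as the
linear de-drift's smoothness assumption wants); the pitch rate uses the
zero-net shape `∝ sin³(πs)cos(πs)` so the foot returns to flat each
stride; forward progression is cycloidal. All segment boundaries snap to
the sample grid and every derivative is analytic, so emitted acceleration,
velocity, orientation and gyro signals are mutually consistent to machine
precision. Sensor corruption inverts the measurement chain: sensor-frame
projection through the mounted orientation, inverse scale/bias, additive
i.i.d. Gaussian noise (drawn then scaled, so recordings with the same seed
and different noise amplitudes share realizations — paired comparisons
stay paired). Default sensor errors, chosen once as typical MEMS values
(none are specified by the protocol): accel noise 0.05 m/s², gyro noise
0.01 rad/s, gyro bias [0.01, −0.02, 0.03] rad/s, scale diag(1.02, 0.98,
1.01), accel bias [0.1, −0.05, 0.02] m/s², mount 5° pitch / 3° roll.

What the generator does **not** emulate: impact transients at heel strike,
micro-motion during stance (its foot-flats are exactly still — real
"foot-flat" is only approximately so), bias instability/random-walk in the
sensors (biases are constant), double support asymmetries, soft-tissue
artifact, and any off-sagittal rotation beyond the mount misalignment.
Passing tests therefore demonstrate correctness of the algorithm under its
own assumptions, not field accuracy on real recordings; realistic trials
violate the zero-motion foot-flat assumption and will sit closer to the
published few-percent NRMSE than to this package's synthetic floor.

## Error floor and noise response

With an ideal sensor the pipeline still shows ≈ 0.34 cm RMSE (≈ 1.7%
NRMSE) on the default walk. Stage-wise decomposition attributes it almost
entirely to the faithful first-order strapdown update (supplying exact
orientations drops the error to 0.002 cm; the prescribed filters
contribute ≈ 0.14 cm). Because this floor is ~25× the contribution of
0.05 m/s² accelerometer noise, the error-vs-noise curve is flat at its low
end, and the *median RMSE* can genuinely dip by ~0.005 percentage points
between noise 0 and 0.05 m/s² (concavity of the root plus threshold
dithering in event detection). The monotone-degradation test therefore
uses a controlled paired design (only the accelerometer noise varies,
common random numbers, event detection frozen), compares adjacent levels
at the median estimator's resolution (0.05 pp) and requires strict growth
across the full range, where the effect is ~30× that resolution.

## Numerical choices

- Trapezoidal integration throughout (exact for piecewise-linear signals;
  the de-drift identities then hold to machine precision).
- `arctan2` for all angle recovery (quadrant-safe; equivalent to the plain
  arctan for a roughly upright sensor).
- Peak matching for trace synchronization: prominence ≥ 20% of the global
  maximum, minimum separation 0.3 s, lag = median offset of matched peaks;
  series are overlap-trimmed before scoring. RMSE is reported in cm and
  NRMSE in percent of the maximum reference clearance.
- Recordings are validated to uniform sampling within 1% jitter and
  strictly increasing timestamps; CSVs are written at full precision
  (`%.17g`) and parsed with round-trip float conversion, so write/read is
  bitwise.
- Degenerate inputs fail loudly with typed, stage-named errors
  (`PipelineStageError`) rather than producing silent zeros — except an
  entirely stationary recording, which is valid and yields an all-zero
  clearance trace.

## Known limitations

- Flat, horizontal ground is assumed; each stride is anchored to zero
  height at its end. Stairs or slopes require adding the known step height
  into the displacement correction and are out of scope.
- Offline only: zero-phase filtering, whole-trial bias estimation and
  stride-terminal corrections all need the complete recording.
- The clearance is that of the sensor (ankle); converting to heel
  clearance is a constant user-supplied offset.
- Very irregular gait (no detectable foot-flat under the thresholds)
  raises a segmentation error instead of guessing; thresholds are
  configurable through `PipelineConfig`.
- Long recordings accumulate strapdown norm inflation (determinant growth
  ∝ exp(Σω²Δt²)); for walks much longer than ~10 m trials, re-anchoring
  orientation at foot-flats would be needed.
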