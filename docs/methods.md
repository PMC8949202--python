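# Methods

`glovecal` implements a calibration-free angle pipeline for bend-sensor
data gloves: per-sensor feed-forward networks trained on a handful of
calibration sample points generate a complete raw-value → angle lookup
table, indexed at runtime by subtracting the wearer's flat-hand reading.
This note records the models, the numerical choices, and what the
simulated evaluation does and does not demonstrate.

## The measurement problem

A glove sensor reports a 12-bit integer (0–4095) that grows
monotonically with the flexion of the joint it covers. The traditional
("linear") calibration captures two poses — flat hand (`raw_min`) and
fist (`raw_max`) — and interpolates:

    theta_linear(r) = theta_max * clip((r - raw_min) / (raw_max - raw_min), 0, 1)

This is exact only if the sensor responds linearly over its whole
range. Real fiber-optic bend sensors saturate, and glove fit (hand
size, loose or tight skin, sensor misalignment) perturbs both offset
and gain, so linear output can be badly biased in mid-range. It also
requires the wearer to make a full fist, which excludes people with
limited joint mobility.

The table method replaces interpolation with a learned inverse of the
sensor transfer function. For each of the 10 joint sensors (index /
middle / ring / little × MCP, PIP; thumb MCP, IP) and each of four
glove hand sizes (7, 7.5, 7.75, 8 inch), a small network is trained on
calibration sample points, then evaluated once at every raw value from
the flat-hand reading up to 4095 to fill a *solution array*. Angles
beyond the joint's physical limit are discarded ("smoothing"), the
array is re-keyed by `raw − flat_hand_raw`, and at runtime

    theta_nn(r) = table[clip(r - flat_hand_raw, 0, len(table) - 1)]

The only per-wearer step is holding the hand flat for a second.

## Network and training

Architecture: 1 input (the raw reading), 7 hidden sigmoid units, 2
sigmoid outputs — one echoes the normalized raw input, one carries the
angle; only the angle output feeds the table. All nodes use
σ(x) = 1/(1+e^{−x}) and have biases. Weights start i.i.d. uniform on
[−0.5, 0.5] from a seeded generator.

Training presents every sample each epoch, accumulates the gradient of
the total error E = ½ Σ_samples Σ_outputs (o − t)² over the batch, and
applies one momentum update per weight:

    Δw(t) = −η ∂E/∂w + α Δw(t−1),   η = α = 0.1

for 100,000 epochs by default. The recorded per-epoch MSE is the mean
(over samples and outputs) squared error; the weights kept are those of
the earliest epoch attaining the minimum MSE, not the final epoch. A
guard aborts if the MSE goes non-finite or exceeds 10× its initial
value. An online (per-sample update) variant is available behind
`NetworkConfig(update="online")` for comparison; the batch rule is the
default because the epoch error is defined over the whole set.

**Normalization.** The raw input is min–max scaled over the training
raws of that sensor, and both targets are mapped into [0.1, 0.9] of the
sigmoid's range (the standard practice for sigmoid output layers:
targets of exactly 0 or 1 sit on the activation's asymptotes, where the
derivative vanishes and gradient descent stalls; with targets on the
asymptotes the nets could not reach degree-level accuracy at this epoch
budget). Predictions invert the affine map. Keys and raw extents still
use the 4095 full-scale constant.

**Training grids.** MCP sensors: 0, 5, 15, 25, 30, 35, 40, 50, 55, 65,
75, 85, 95° (13 points); PIP-class sensors (including the thumb IP)
additionally 105° (14 points). Calibration poses are held static and
averaged, so sample points are simulated noiseless by default. The 0°
sample anchors the minimum of each sensor's scale and is never removed
by the subset search.

**Leave-one-out subset search.** Optionally, the training set is
re-trained once per leave-one-sample-out candidate (0° excluded from
removal) at a reduced 10,000-epoch budget; the subset with the lowest
best-epoch MSE wins (ties to the larger set) and is retrained at the
full budget. This mirrors pruning redundant sample points that can trap
training in local minima.

**Implementation.** The epoch loop is compiled with numba; a plain
numpy implementation of the identical update serves as the reference
(`backend="numpy"`), and a test asserts the two produce the same MSE
trace to 1e-12. The analytic gradient is exposed separately
(`loss_and_grads`) and checked against central finite differences
(step 1e-6) to below 1e-6 relative error.

## Table construction

* Solution array: raws `flat_hand_raw … 4095` in unit steps.
* Fill: one network evaluation per raw; negative predictions clamp to 0.
* Zero reference: the flat-hand reading *defines* 0°, so the network's
  small residual at the first entry (up to a few degrees at this epoch
  budget) is subtracted at key 0 and tapered out linearly by the point
  the table has risen 5° above it. Key 0 then reads exactly 0°, the
  correction adds an increasing ramp (monotonicity preserved), and the
  rest of the table is untouched. Subtracting the residual from the
  whole table instead was measured to *worsen* mid-range accuracy and
  was rejected.
* Smoothing: entries after the first angle exceeding the joint limit
  (95° MCP, 105° PIP) are removed; retained angles clamp into
  [0, theta_max]. No monotonicity repair is applied inside the physical
  range — anomalies are surfaced by the `is_monotone` diagnostic rather
  than silently edited.
* Normalization: key = raw − flat_hand_raw; banks store 10 tables per
  hand size, addressed by (hand_size, sensor_id).

Typical accuracy at the defaults, measured by the acceptance script
(`recovery_mae_*`): mean absolute error ≈ 0.8° over the 0/20/45/60/70/90°
test grid, worst case ≈ 1.3–2.0° across all 120 sensor × hand-size ×
curvature combinations. Interior training points fit to <1° for linear
sensors; errors are largest (2–5°) at the very top of the grid, where
the sigmoid output flattens — the physical test grid tops out at 90°,
inside the well-fit region.

## Simulated glove

No glove hardware is involved; the simulator generates data with the
statistical structure the method assumes:

* Transfer function `raw(θ) = round(clamp(r_flat + fit_offset +
  gain·fit_gain_scale·g(θ/θ_max; c) + ε, 0, 4095))` with
  `g(u; c) = (1+c)u/(1+cu)` — the simplest one-parameter monotone
  family with g(0)=0, g(1)=1, identity at c=0 and front-loaded
  (saturating) for c>0. Defaults: curvature 0 (tests choose 0/1/3),
  ε ~ N(0, noise_sd²) per frame (0 by default; protocol scenarios use
  ~4 counts), 12-bit quantization.
* Hand fit: per-sensor additive offsets and multiplicative gain
  perturbations drawn with SD proportional to the distance of the hand
  size from the glove's 7.75-inch design size (60 counts and 0.08
  log-gain per inch) — the 7-inch hand is the worst fit, matching the
  observation that a small hand in a medium glove couples loosely to
  the sensors. Donning/doffing adds a fresh per-sensor offset
  ~ N(0, don_doff_sd) each re-donning.
* Thumb sensors default to 3× the base noise, standing in for the
  difficulty of stabilizing the thumb against a mold.
* Test protocols at 50 Hz: A (flat/rest holds ×10, glove kept on),
  B (flat/fist ×10), C (as B with re-donning drift per cycle),
  D (holds on 0/20/45/60/70/90° blocks), E (12 maximal-flexion ramps).
  Holds default to 5 s (250 frames).

What the simulator does **not** model: sensor hysteresis and creep in
the glove material, cross-coupling between adjacent MCP sensors, the
four abduction/adduction sensors, hyperextension (grids start at 0°),
left hands, and the idiosyncrasies of any particular wearer's
anthropometry. Passing the simulated suites therefore shows the
*method* is implemented correctly and behaves as intended under the
assumed error structure — it does not certify accuracy on any physical
glove or human hand.

## Evaluation statistics

* Repeatability: range (max − min) and SD of per-cycle means. SD uses
  the sample (n−1) estimator throughout.
* Pearson correlation: both r and r² are reported (tables of this kind
  are often labelled ambiguously).
* Bland–Altman: mean difference ± 2·SD of paired differences.
* Mean difference with 95% CI: t-based, mean ± t₀.₉₇₅,ₙ₋₁·sd/√n —
  appropriate at the n = 12 flexions of the maximal-ROM protocol.
* Benchmark harness: per seed, trains a fresh table bank, calibrates
  the linear baseline from a flat+fist recording, runs the requested
  protocols, and tabulates per-sensor statistics for both methods.

Under the default comparison scenario (7-inch hand, curvature 3, noise
SD 4 counts, 20 seeds) the table method beats the linear baseline on
block-angle accuracy in 100% of seeds and has a smaller mean flat-pose
range — the qualitative behaviour expected when sensor response is
nonlinear, since min–max interpolation is systematically biased
mid-range while the table inverts the response pointwise.

## Problem sizes and determinism

The acceptance script trains 120 networks for the recovery sweep plus
20 × 10 for the method comparison, all at the full 100,000-epoch
budget (a training run takes ~0.3 s compiled), and completes in a few
minutes on one CPU. Every random quantity — weight initialization, fit
profiles, frame noise, drift — flows from explicit integer seeds;
repeated runs with the same seed are bit-identical. The first call in
a fresh environment pays a one-time numba compilation cost of a few
seconds.

## Known limitations

* The two-output architecture (echo + angle) follows the original
  design; the echo output consumes some capacity without aiding the
  table. A one-output variant exists (`n_outputs=1`) but is not the
  default.
* Tables are discrete in raw counts; angular resolution is bounded by
  theta_max/gain degrees per count (~0.06° at default gains).
* No interpolation between hand sizes: a wearer between sizes gets the
  nearest bank.
* Smoothing trusts the network's monotonicity inside the physical
  range; a pathological net could yield a non-monotone table, which is
  flagged but not repaired.
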