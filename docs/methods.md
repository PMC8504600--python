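# Methods

`profile_restore` reconstructs continuous, volume-averaging-free photon beam
profiles from the discrete readings of an ionization-chamber array.  This
note records the models, the numerical choices, and the limits of what the
synthetic experiments demonstrate.

## The measurement problem

A chamber array of the ICProfiler class samples a beam profile at a 5.0 mm
pitch (65 detectors on the Y axis over ±160 mm; 63 on the X axis, whose
±5 mm positions are absent), and each chamber averages dose over its ~2.9 mm
extent along the scan direction.  Both effects widen the apparent penumbra:
the 20–80% width of a measured and interpolated profile exceeds that of a
point-detector reference scan by 1–2.5 mm depending on plane and depth (the
penumbra-width difference, PWD = W_o − W_r).  The package's pipeline is

1. **Makima upsampling** of the discrete readings to a 0.5 mm grid, and
2. a **sliding-window shallow network** that maps each 1.5 cm window of the
   upsampled curve to the volume-averaging-free dose at the window center,

    O = σ_o( Σ_k w⁰_k · σ_h( Σ_j wʰ_jk s_j + bʰ_k ) + b⁰ ),

   with σ_h = tanh and σ_o the identity; sliding the window one grid step at
   a time yields the reconstructed profile.  The half-window margins at each
   end copy the input, and the result is renormalized to 1.0 on the axis.

## Makima interpolation

Knot slopes are the weighted secant average
d_i = (w₁ δ_{i−1} + w₂ δ_i)/(w₁ + w₂) with
w₁ = |δ_{i+1} − δ_i| + |δ_{i+1} + δ_i|/2 and
w₂ = |δ_{i−1} − δ_{i−2}| + |δ_{i−1} + δ_{i−2}|/2, boundary secants extended
by the quadratic rule δ_{−1} = 2δ_0 − δ_1 (and symmetrically); d_i = 0 when
the weights vanish.  Evaluation is cubic-Hermite on these slopes.  The |sum|
terms damp the flat-spot artifacts of classic Akima while keeping its
overshoot suppression, which is why the scheme is preferred over an ordinary
spline on beam profiles.  Non-uniform knots are supported, which handles the
X axis's missing central detectors without imputation.  Extrapolation beyond
the outermost detectors is an error, not a clamp.  The implementation is
checked against an independent reference implementation to 1e−9 on random
fixtures.

## Synthetic ground truth

No measured data ship with the package; a physics-based generator stands in
for the linac measurements.  The dose model per geometry is a **dual-source
edge**: each field edge is (1 − w)·erf-edge(σ_core) + w·erf-edge(σ_scatter),
with w = 0.375 and σ_scatter = 7 mm representing extra-focal radiation and
phantom scatter, and σ_core(plane, depth) the focal-source penumbra scale.
The envelope is modulated by flattening-filter structure — Gaussian horns of
relative amplitude +3%/+1.5% at 1.5/5 cm depth and a −2% shoulder at 10 cm
(the beam is flattened for 10 cm depth, so shallower depths show horns and
deeper ones a slight rounding).  Horn/shoulder amplitude scales with the
square of the edge off-axis distance (reference: the 10 × 10 cm² edge), so
small fields are horn-free, as physically expected.  An out-of-field tail of
0.5%/1.2%/2.2% at 1.5/5/10 cm represents transmission plus depth-accumulated
phantom scatter.  A single-erf family was tried first and rejected: matching
the published baseline PWDs forced sub-millimetre core scales (unphysical
for 6 MV) and made the window-to-dose mapping needlessly stiff.

Field edges are placed at (field/2)·(SSD + depth)/100 with SSD = 90 cm.
This projection makes every depth-10 field edge coincide exactly with a
detector position — the same sampling-phase coincidence that produces the
large, low-variance baseline PWDs observed at 10 cm depth on the real
device, so the convention is retained even though the physical array plane
is fixed and only the radiological depth changes.

**Volume averaging** is convolution with a unit-area 1-D rectangular kernel
of width 2.9 mm (the chamber extent along the gradient), evaluated exactly
for the piecewise-linear profile on its grid; the full 2-D chamber cross
section is ignored because the orthogonal direction is locally flat at first
order.  **Sampling** reads the averaged profile at the detector positions
(linear interpolation), optionally with a setup offset (|Δ| ≤ 2.5 mm) and
multiplicative Gaussian noise (default 0 — the reference measurements are
high-dose, low-noise), then renormalizes to the reading nearest the axis.

### Calibration of the shipped defaults

The free per-(plane, depth) core scales are fixed by a one-time root search:
σ_core is solved so that the forward chain (truth → 2.9 mm aperture → 5 mm
array → Makima at 0.5 mm) reproduces the published mean baseline PWD for
that plane and depth (in-plane 1.6/1.8/2.4 mm, cross-plane 1.2/1.2/1.6 mm at
1.5/5/10 cm), averaged over the seven field sizes, to within 0.05 mm.  The
search (`calibrate_defaults`, re-runnable via `scripts/calibrate_defaults.py`)
yields

| plane | 1.5 cm | 5 cm | 10 cm |
|-------|--------|------|-------|
| in    | 1.107  | 1.191 | 1.413 |
| cross | 1.961  | 2.068 | 1.989 |

(mm).  In-plane cores are smaller than cross-plane at every depth,
consistent with jaw-defined versus MLC-defined edges, and the resulting
20–80% truth widths (≈2.3–4.8 mm) are in the physically observed range.
The per-field spread of baseline PWDs emerges from sampling phase alone:
large and uniform at 10 cm (phase-0 alignment), smaller with ±0.6–0.7 mm
spread at shallow depths — the same signature as the published per-depth
statistics.

## Network training

Pairs are extracted by sliding a 31-tap (15 mm at 0.5 mm) window over each
upsampled training measurement; the target is the ground-truth dose at the
window center (truth decimated from the 0.1 mm simulation grid, which
contains the 0.5 mm grid exactly).  The default experiment trains on the
{2, 4, 6, 10} cm² fields at all depths and planes (24 profiles, 14 664
pairs) and holds out {3, 5, 8} cm² entirely.  Pairs are partitioned
70/15/15 (train/validation/test) uniformly at random, seeded.

Training is batch Levenberg–Marquardt: per epoch the damped normal equations
(JᵀJ + μI)Δ = Jᵀr are solved with the analytic Jacobian; μ is divided by 10
after an accepted (loss-reducing) step and multiplied by 10 otherwise, with
μ₀ = 1e−3 and a 1e10 ceiling.  Training stops at 400 epochs, when six
consecutive epochs fail to improve the validation MSE, when the gradient
max-norm falls below 1e−10, or when no downhill step exists at the μ
ceiling.  Ten restarts from random initializations (Gaussian weights scaled
by 1/√fan-in; Nguyen–Widrow initialization was benchmarked and performed
equivalently) guard against local minima; the restart with the lowest
validation MSE is kept.  Inputs enter unscaled (they are already ~[0, 1.05]
relative dose).  An "epoch" is one LM iteration over the full training
partition.  The per-restart seeds derive from the configuration seed, making
training bit-reproducible.

The hidden-node sweep retrains at N_hn = 2…20 (step 2) and records the
minimum validation MSE per size; 18 is shipped as the default.  In the
acceptance suite the sweep is run at its endpoints {2, 18} with two restarts
— enough to pin the monotone trend the full sweep shows.

## Metrics

* **MSE** — plain mean squared difference (the training objective).
* **Penumbra / PWD** — the profile is first re-centered at the midpoint of
  its two 50% crossings (robustness to setup offsets); 20% and 80% of the
  central-axis value are located per side by linear interpolation searching
  outward; the per-profile width is the mean of the two sides, and
  PWD = W_o − W_r is signed.  Summaries report mean ± SD of signed PWDs and
  mean |PWD| separately (the published tables do not disclose sidedness or
  sign handling; the mean-of-sides choice is symmetric and stable).
* **1-D gamma (1%/1 mm)** — global normalization to the reference maximum,
  10% low-dose threshold, search window ±3·DTA.  The evaluated curve is
  resampled at 0.1 mm and γ is minimized exactly over the resulting polyline
  (point-to-segment distances in scaled coordinates), which avoids the
  aliasing a pointwise search suffers in steep gradients.

## What the experiments show — and their limits

With the shipped defaults, per-(plane, depth) specialist networks and
plane-specific networks (18 hidden nodes) essentially solve the synthetic
task: training MSE ~1e−8…1e−7, mean |PWD| 0.002–0.06 mm, gamma ≥ 99.8%,
including the field sizes excluded from training.  The **combined** network
— one model for both planes, the headline configuration — must multiplex six
slightly different inverse filters through the same 18 hidden units and
plateaus at a training MSE of ~3e−6 under the 400-epoch protocol (a
2000-epoch run reaches only ~2.4e−6, so the plateau is capacity, not epoch
budget).  In the default run its reconstructions cut the per-(plane, depth)
mean |PWD| from 1.18–2.37 mm to 0.09–0.29 mm (an 8.6× mean reduction;
largest single-geometry |PWD| 0.50 mm) with a 100% 1%/1 mm gamma pass rate
on every geometry: a large restoration, but short of the near-perfect
figures the plane-specific models reach.  On the real device the combined
and plane-specific networks performed nearly identically; in this synthetic
analog the per-plane contrast in required correction is evidently harder.
Users targeting the last 0.1 mm should prefer plane-specific models
(`--plane in|cross`), which the pipeline trains by default.

The generator emulates: divergent square fields, jaw/MLC plane asymmetry,
horn/shoulder structure, depth-dependent scatter tails, the exact detector
layouts, and the rectangular volume-averaging kernel.  It does not emulate:
measurement noise and day-to-day setup variation (available but off by
default), detector-to-detector calibration differences, energy response,
the 2-D chamber cross-section, density perturbation by the array, diagonal
axes, or fields beyond 10 × 10 cm².  Passing the synthetic suite therefore
demonstrates the correctness of the algorithmic chain and its statistical
behaviour under the modeled physics, not clinical performance on any
particular linac.

## Numerical choices and degenerate inputs

* Fine simulation grid 0.1 mm over ±170 mm (≪ aperture and penumbra
  scales); reconstruction grid 0.5 mm over ±160 mm (31-tap window = 15 mm).
* Volume averaging requires grid step ≤ aperture/4 and rejects apertures
  wider than the profile support; aperture 0 is the identity.
* Makima requires ≥ 4 strictly increasing knots; duplicate positions are
  errors; zero-weight slope denominators give d_i = 0.
* Penumbra crossing search reports which side failed when a threshold is
  never crossed (truncated or too-narrow profiles).
* LM raises μ and retries on a singular normal matrix; a non-finite loss
  aborts the restart with a diagnostic rather than poisoning the selection.
* Calibration detects a flat objective (chain insensitive to σ) and reports
  the PWD span and monotonicity when a target is unreachable inside
  σ ∈ (0.5, 6) mm.
* All randomness flows from explicit seeds through `numpy` SeedSequence
  spawning; dataset generation, training and reports are bit-reproducible.
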