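# Methods

## The measurement model

A jump of a small (~mg) larva is filmed side-on at a high frame rate and
reduced to a planar centre-of-mass path. Four phases are distinguished:

1. **loading** — slow dorsal body arching while the legs grip the
   substrate, presumed elastic energy storage;
2. **latch decoupling** — from the first leg starting to lose grip to the
   last leg leaving the ground;
3. **launch** — from last-leg release to the end of all body–substrate
   contact;
4. **airborne** — free flight to landing.

Phase boundaries are manual inputs (frame indices); windows are half-open
`[start, end)` so a boundary frame belongs to the later phase and per-phase
displacement shares sum exactly. Latch decoupling and launch are pooled for
the power calculation because in practice they overlap heavily; pooling
lengthens the power window and therefore biases power estimates
conservatively low.

All per-jump energetics use a cohort-average body mass when individual
masses cannot be resolved on the balance — the default morphometrics are
the observed cohort averages (m = 1.3 × 10⁻⁶ kg, body length 5.55 mm,
muscle volume 0.12 mm³ at an assumed 1060 kg m⁻³, giving a 9.78% muscle
mass fraction).

## Tracking front end

Frames are binarised at a fixed global threshold (dark-on-light by
default); the largest 8-connected component is the animal and its
binary-mask area centroid the centre-of-mass estimate. Equal-size largest
components are tie-broken by proximity to the previous centroid, with a
warning. The pixel scale comes from a calibration grid of known spacing
(default 5 mm) measured in pixels; grid auto-detection is deliberately not
implemented, since grids are measured offline at much higher precision
(~1 µm). Image row coordinates are inverted at import so y increases
upward. Reorientation translates the first sample to the origin and
mirrors x if the net horizontal displacement is negative; the reflection is
recorded so takeoff angles can also be reported in the raw camera frame as
180° − α.

The centroid is binary-mask based, not intensity weighted, matching a
thresholded-silhouette workflow. Sub-pixel blob fitting, multi-object
tracking and video codecs are out of scope (image sequences only).

## Ballistics

A least-squares parabola y = ax² + bx + c is fitted to the airborne
samples (unconstrained intercept). Apex height is the **vertex
y-coordinate** h = c − b²/(4a); a widely circulated shorthand quotes
−b/(2a), which is the vertex *x*-coordinate, and that variant is available
only behind `apex_height(..., convention="vertex_x")` for comparison.
Horizontal distance is the larger real root of the quadratic; takeoff
angle is tan⁻¹(b), in (0°, 90°] after reorientation. Drag, lift and
out-of-plane motion are ignored: a single camera view underestimates
horizontal distance for jumps not parallel to the image plane.

## Spline differentiation and the smoothing default

Velocity and acceleration come from a cubic smoothing spline of the
cumulative path displacement (scipy's `make_smoothing_spline`), maximised
over the pooled latch + launch window extended one frame into the airborne
phase (the first airborne sample is the takeoff instant; one extra frame
tolerates annotation slack).

The penalty default is **λ = 1e-9** (on the integrated squared second
derivative, time in seconds). A cubic smoothing spline's equivalent kernel
bandwidth scales as λ^¼ ≈ 6 ms, comparable to the pooled launch window:
small enough to resolve the takeoff transient, large enough to suppress
sub-millisecond tracking jitter. Generalised cross-validation is available
(`smoothing="gcv"`) but is **not** the default: these series are dominated
by a ~0.2 s quasi-static loading phase, so GCV tunes itself to the flat
segment and oversmooths the millisecond-scale launch, underestimating
takeoff speed by tens of percent. A fixed, physically motivated bandwidth
is the honest choice, mirroring how such spar values are chosen visually in
practice.

## Energetics and the LaMSA test

E = ½mv² (v = spline v_max), P = mL²/t³ (average power over the pooled
window), O(c) = P/(mc). O(c)·c is constant per jump, so threshold flags
are monotone in c. The 400 W kg⁻¹ ceiling (the highest maximum average
power density measured from muscle, vertebrate flight muscle) is a
configurable reference, not a constant of nature. The critical fraction
c* = (P/m)ₘₐₓ/400 is the exact flag boundary: at any c > c* no jump
exceeds the ceiling.

COT_jump = (1/η)·E/(md) with η = 0.10; COT_crawl = 10.8·m⁻⁰·³² (allometric
regression for legged arthropods, m in kg). The cohort COT_jump can be
reported either as the mean of per-jump values or as the formula applied
to cohort means; the two differ under Jensen's inequality and outputs are
labelled accordingly.

Inputs grossly outside declared units trigger a warning heuristic
(mass > 1 kg or < 10⁻⁹ kg), catching mg-for-kg mistakes.

## Uncertainty

First-order independent quadrature from three primary relative
uncertainties — length (default: one pixel over the launch displacement),
time (one frame interval over the window duration) and mass (0.1 mg
balance resolution over body mass):
u_v/v = √((u_L/L)² + (u_t/t)²), u_a/a = √((u_L/L)² + (2u_t/t)²),
u_E/E = √((u_m/m)² + (2u_v/v)²), u_P/P = √((u_m/m)² + (2u_L/L)² + (3u_t/t)²),
power density adds (u_c/c)². Correlations between inputs are neglected.

## The synthetic generator

Defaults are the observed study conditions: 3,200 frames s⁻¹, takeoff
0.47 m s⁻¹ at 79.6°, loading 0.22 s, latch 5.5 ms, launch 1.4 ms, launch
displacement 1.3 mm, pixel scale 20 µm px⁻¹ and 0.3 px centroid noise.

- **Pixel scale.** Chosen from the filming geometry: near-1:1 macro
  magnification onto a 1280 × 720 sensor puts the 0.5 cm grid at ~250 px,
  i.e. 2 × 10⁻⁵ m px⁻¹. At much coarser scales per-frame steps become
  sub-pixel for slow jumps and path-length quantisation inflates recovered
  speeds — a genuine failure mode of path-integrated displacement, worth
  knowing when planning recordings.
- **Loading** is a smoothstep rise of configurable amplitude (default
  0.3 mm): only its duration and displacement share matter downstream, so
  no force law is asserted.
- **Latch + launch** is a monotone power-law ramp s(τ) = L(τ/T)^q with
  q = vT/L, which delivers exactly L of path length and ends at exactly
  speed v, making the transition into ballistic flight
  velocity-continuous. No spring/latch forward dynamics are modelled.
- **Airborne** samples follow ideal projectile motion for the ballistic
  flight time 2v·sinθ/g.
- Coordinates are quantised to the pixel grid, then perturbed with seeded
  isotropic Gaussian noise in pixel units — emulating thresholded-centroid
  jitter. Generation is bit-reproducible per seed.
- Cohort generation draws timing parameters per larva and takeoff speed
  and angle per jump from the observed ranges (0.14–0.87 m s⁻¹, 30–110°).
  Unless given its own range, launch displacement is drawn as 0.35–0.8 of
  v·T so the pre-airborne ramp stays kinematically plausible.
- The renderer draws an anti-aliased dark ellipse over a light gridded
  background; the mask centroid matches the true centroid within 0.5 px.

What the generator does **not** emulate: body shape change during loading
and launch (the real centroid wanders within the silhouette as the larva
curls), 3-D body rotation (pitch/roll/yaw), motion blur, lighting drift,
background clutter, and out-of-plane trajectories. Passing recovery tests
therefore demonstrates correctness of the estimation chain under the
stated noise model, not robustness to every artefact of real footage.

## Test problem sizes

Validation cohorts use 30 jumps (10 larvae × 3) per condition, with
parameter recovery judged by median relative error — robust to the
expected heavy tail from near-vertical or slow jumps, where a y-vs-x
parabola is ill-conditioned and per-frame steps approach the noise floor.

## Known limitations

- Takeoff angles > 90° (backward-leaning jumps) are reported in (0°, 90°]
  after reorientation unless the raw-frame convention is requested.
- Phase annotation is manual; the bundled velocity-threshold detector is
  an experimental convenience, not a validated method.
- Path-integrated (cumulative) displacement is used for L and for the
  spline, by design; it is upward-biased when per-frame steps are
  comparable to tracking noise.
- The airborne duration implied by ballistics, 2v·sinθ/g, is the
  generator's definition of flight time; printed summaries elsewhere that
  conflict with their own speeds and ranges are not reproduced.
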