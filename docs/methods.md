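# Methods

`echoroll` simulates a developmental model of sonar-based sound
localization in an echolocating bat.  A simulated agent emits
frequency-modulated calls, receives binaural echoes from a fixed-range
target filtered through head-related transfer functions (HRTFs), encodes
the echoes with learned subspace dictionaries (GASSOM), and learns —
from the coding efficiency of its own representation, with no access to
the true target direction — a head-control policy that orients the head
toward the target.  Random head rolls drawn from an autoregressive model
of measured bat head waggles rotate the interaural axis between echoes.
This note records the model, its parameters, and the design choices made
where the design was genuinely open.

## Coordinates and kinematics

Body and head frames are right-handed with X forward, Y left, Z up.
Positive yaw turns the head left, positive pitch up, positive roll
brings the right ear down.  A head pose is the Fick composition
`R_HB = R_Z(yaw) R_Y(pitch) R_X(torsion)`; its transpose maps the
target direction into head coordinates.  Directions are reported as
(horizontal angle α, elevation φ), with `α = asin(sin θ cos φ)` for
azimuth θ — the coordinate constant on a cone of confusion, and the one
in which HRTFs are gridded.  The pair (α, φ) is geometrically valid only
where `sin²α + sin²φ ≤ 1` (the frontal hemisphere); target sampling and
probing grids respect this.

Per-iteration yaw/pitch commands update an accumulated body-to-head
matrix through passive incremental rotations (so a positive yaw command
moves the head toward positive azimuth); the matrix is re-projected onto
SO(3) every step (SVD) to stop floating-point drift.  The head-direction
torsion follows Listing's law, `γ_list = yaw · pitch / 2` with the
product evaluated in radians (the standard small-angle form; the
degree-product alternative produces physically absurd torsions), and the
active roll sample is added to it.  Gimbal lock (|pitch| = 90°) raises
an error; tolerance 1e-6 deg.

Marker-based pose estimation reconstructs the Fick pose from a (left
pinna tip, right pinna tip, head) motion-capture triplet: the Z axis of
the marker frame runs from the head marker through the orthocenter of
the marker triangle (hence perpendicular to the inter-pinna line, which
makes the estimate insensitive to symmetric pinna raising/lowering), the
Y axis is the marker-plane normal, X their cross product.  The pose is
the rotation carrying a reference template onto the observed frame;
recovery of random poses from noiseless markers is exact to < 1e-6 deg.
The estimator is per-frame; no smoothing is applied.

## Head-roll model

Echo-to-echo head roll is a stationary Gaussian AR(p) process, one
sample per received echo.  Fitting matches the model-implied
autocorrelation function (ACF) to the sample ACF over lags 1–40 by least
squares; the search runs over tanh-transformed reflection coefficients
(Durbin–Levinson parametrization), so every candidate is stationary by
construction, and stationarity is tested by the Schur–Cohn criterion
(numerically robust where near-unit polynomial roots are not).  The
innovation variance is set so the marginal standard deviation equals a
requested calibration value; simulated conditions use σ ∈ {0, 10, 20,
30} deg, with σ = 0 implemented as the degenerate all-zero stream.

Order selection is cross-validated: five contiguous blocks, each fold
fitting on 80% (ACFs of the contiguous chunks averaged with length
weights, never spliced) and scoring the fitted coefficients'
one-step-ahead prediction error on the held-out block; the selected
order is the smallest within one standard error of the best.  We first
scored folds by validation-ACF squared error, but that score's floor is
set by the validation ACF's own sampling noise, which is flat across all
orders at or above the true one, so order recovery failed; prediction
error shares its sampling noise across orders within a fold, letting the
parsimony penalty decide.  On synthetic AR(5)/AR(2)/white-noise series
of length 1e4 the scheme recovers the true (smallest) order in ≥ 9/10
runs.

The default calibrated AR(5) model is a stand-in, not a published
coefficient set: it is produced by fitting the package's own estimator
to a smooth reference ACF (`exp(-k/10) · cos(2πk/60)`, decaying within a
few tens of echoes with a mild negative tail, qualitatively matching the
measured roll ACF) and calibrating to σ = 10 deg, the measured roll
standard deviation.

## Auditory synthesis

Calls are linear downward FM sweeps 70 → 15 kHz sampled at 500 kHz,
duration drawn from Γ(shape 8.0, scale 0.3) ms — mean 2.4 ms, std
0.85 ms.  Echoes are the call convolved per ear with the HRTF
interpolated at the target's head-centred direction, then jointly
normalized: both channels divided by the RMS of the concatenated stereo
pair, preserving the interaural ratio exactly while discarding overall
magnitude (target range is fixed at 1 m; no distance attenuation,
propagation delay, emission directionality, clutter, or absorption).

### Synthetic HRTFs

Measured bat HRTFs are not shipped; the package generates a synthetic
spherical-head set on a (horizontal × elevation) grid (default ±85° at
5–10° spacing, impulse responses of 128 taps built in the frequency
domain).  Components, per direction and ear:

* **ITD** — Woodworth delay `a(α + sin α)/c` with head radius a = 7 mm
  and c = 343 m/s, split ± between the ears around a 64 µs base delay;
  span ≈ ±52 µs at ±90°, consistent with the ±80 µs probing range.
* **ILD** — saturating sin-law head shadow: ±(sin α / 2) · S ·
  f/(f + 20 kHz) dB with span S = 10 dB.  We first used a
  Brown/Duda-style first-order shadow filter whose far-ear gain
  (1 − sin α) collapses lateral echoes to near-monaural; because the
  reconstruction error of a nearly one-eared window is intrinsically
  low, that design made *lateral* directions the easiest to encode and
  inverted the error-surface geometry the model's mechanism needs.
* **Elevation notch** — a Gaussian spectral notch whose center sweeps
  35 → 65 kHz over elevation ±40° (depth 0.8, width 3 kHz), a monaural
  elevation cue as with real pinnae.
* **Pinna reflection** — `1 + ρ e^{-2πif τ_r}` with ρ = 1.2 · sin(ecc)
  (zero on-axis) and delay τ_r = 25 µs · (1 + 1.5(1−x) + 0.8(±y) +
  0.6z) varying with direction and ear.  Like measured ears, the
  response is spectrally smooth straight ahead and increasingly
  comb-structured off-axis; this gives the reconstruction-error surface
  an intrinsic minimum toward the front, and makes the roll state
  observable in the spectra.  Without it, a uniformly-exposed dictionary
  found all directions equally easy and the closed loop settled into a
  degenerate constant-drift policy (sweeping the scene predictably is
  also "efficient coding").

The set is exactly symmetric about the median plane.  Rendered-echo
cues re-measured by cross-correlation/energy ratio recover the set's
generating values within 2 µs / 0.5 dB across the grid (call-band
limited).  Interpolation is bilinear in per-bin magnitude and unwrapped
phase and is exact at grid nodes.  What the generator does **not**
emulate: individual variability (the measured data had three bats),
front–back asymmetries, frequency-dependent ITD, and measurement noise —
so behavioral results under it show that the mechanism operates, not
that its effect sizes match the measured-HRTF system.

### Cochlear front-end variant

An alternative input representation: per ear, an 81-channel bandpass
bank uniformly spaced 20–100 kHz (4th-order Butterworth sections, 2 kHz
half-power bandwidth — a documented stand-in, the source model names no
family), half-wave rectification, and a first-order 1 kHz lowpass
(positive impulse response, so envelopes stay non-negative).  Windows of
100 µs with 10 µs stride, each downsampled by 10, both ears
concatenated: 2 × 81 × 5 = 810 dimensions per window.

## Perceptual representation (GASSOM)

Echo pairs are cut into fine (50-sample) and coarse (100-sample,
decimated by 2) windows with stride 5, for binaural (concatenated,
dimension 100), left, and right (dimension 50) streams — six streams in
all, each with its own GASSOM.  Windows are normalized to unit norm
(scale-free errors); windows below 1e-6 of the batch's maximum norm are
dropped so numerically-silent convolution tails never enter.

Each GASSOM unit j is a two-column orthonormal basis Φ_j; the response
to window x is ‖Φ_jᵀx‖² and the reconstruction error E_j = ‖x‖² −
response (the projection identity holds to 1e-10 against explicit
projection matrices).  Soft assignment combines the Gaussian likelihood
`exp(-E_j / 2σ_n²)` with a sticky first-order Markov prior over
consecutive windows (stay probability 0.9) — the temporal-smoothness
constraint — in a causal forward pass.  Learning pulls each unit toward
the windows assigned to it and to its grid neighbours (Gaussian
neighborhood on a square unit grid), then re-orthonormalizes by QR.  The
per-unit pull is normalized by the unit's total assignment weight
(batch-SOM convention); without this the step scaled with the window
count (~230 per echo) and the dictionary thrashed.

Schedules (annealed geometrically over the training horizon): learning
rate 0.3 → 0.02, neighborhood radius 1.0 → 0.5 on the 8×8 scaled grid
(2.5 → 0.5 on the full 20×20 grid; a radius of 3 on the small grid
homogenizes the map), σ_n 0.4 → 0.15.  These hyperparameters are not in
the source model description and are tuned for stable convergence, not
claimed canonical.

Per echo, each GASSOM's responses are average-pooled over windows and
the six vectors concatenated: the feature f(t), dimension 2400 at full
scale (six × 400 units), 384 under the scaled profile (six × 64).

## Reward and head control

The reward is the negative reconstruction error averaged over scales,
streams and windows, `r(t) = -(1/6N) Σ_s Σ_e Σ_i E_{s,e,i}(t)`,
implemented as the mean of per-stream means (identical when streams have
equal window counts, and robust when convolution-tail dropping makes
them differ by a few).  Per-window errors are posterior-weighted over
units.

The actor maps f(t) — standardized per vector (zero mean, unit
variance), since raw pooled responses (~2/dim) would leave tanh units in
their dead zone — through one tanh hidden layer (500 units full scale,
100 scaled) to the means of the yaw/pitch commands; training actions are
drawn with exploration std σ_e = 10 deg and clipped at ±30 deg/iteration,
testing uses the greedy mean.  The critic is linear.

Updates are natural actor-critic with compatible features:

* **Critic** — recursive-least-squares TD(0) with forgetting 0.999 (the
  least-squares critic of the episodic NAC lineage); a plain LMS TD(0)
  option exists and is used by closed-form unit tests.  Plain LMS could
  not track the value function under the drifting representation.
* **Actor, output layer** — the TD error is regressed (RLS, forgetting
  0.995) onto ψ = ∂log π/∂(mean parameters); by the
  compatible-function-approximation theorem the fitted coefficients are
  the natural gradient of the mean parameters, applied every 20 steps
  after a warm-up of twice the feature count, with a trust-region cap of
  1 deg on the induced change of the action mean.
* **Actor, hidden layer** — vanilla back-propagated score-function
  gradient at rate 1e-3, annealed ×0.1 over training.

Discount is 0.3 (short-horizon episodic task); no bootstrapping across
target changes.  Divergence (policy weight norm > 1e4) raises an error.

## Closed loop and profiles

One iteration = one call/echo and one head update: roll sample → Fick
pose (Listing + roll) → target in head coordinates → echo → windows →
encoding → pooled feature and reward → action → head update.  A target
direction is held for 20 iterations, then redrawn uniformly over the
target region (±60° horizontal × elevation, restricted to the feasible
part of the hemisphere); episodes truncate with a flag if the target
leaves the HRTF hull.  Rolls advance once per echo in every mode.
Episode k of a run derives all randomness from SeedSequence([seed, k]),
so interrupted runs resume bit-identically from checkpoints (HDF5:
dictionaries, both networks including the RLS states, HRTF set).

Two profiles: `ci` (64-unit GASSOMs on 8×8 grids, 100 hidden units,
HRTF grid at 10°, default 600 training targets) and `full` (400 units on
20×20, 500 hidden, 5° grid, default 10000 targets).  The scaled profile
is the package's working scale for its test battery; the behavioral
comparisons there train 1000 episodes (20000 iterations) per roll
condition from one fixed seed and take medians over independent
evaluation seeds.  At this scale the behavioral effects of rolls are
reproduced as orderings (which condition is better), not effect sizes;
closed-loop co-development is volatile across training seeds at small
dictionary sizes, and a single scaled run can land on a displaced
attractor, which is also the phenomenology of the zero-roll condition at
full scale.

## Analysis battery

* **Step-response fits** — s(t) = A e^{−t/τ} + B by nonlinear least
  squares with multi-start over τ (linear pre-solve for A, B per start);
  τ at the [1e-3, 1e3] bound is flagged.  Exact on noiseless data;
  median τ̂ within 10% under 1-deg noise.
* **Steady-state MSE** — mean of (horizontal² + elevation²) at the final
  iteration, optionally normalized by the σ = 0 reference.  The measure
  is rotation-invariant, so roll jitter at the final iteration does not
  inflate it directly.
* **Basis characterization** — both components of a binaural basis
  vector are fitted with a shared Gaussian-windowed linear chirp
  (center frequency, sweep rate, envelope center/width) and per-component
  amplitude/phase (linear sub-solve); ILD = 20 log10 amplitude ratio,
  ITD = carrier phase difference / 2πf_c wrapped to half a cycle
  (positive = left leads).  Round-trip accuracy 0.2 dB / 0.5 µs within
  half a carrier cycle.
* **Pure-tone probing** — best frequency from 10–70 kHz in 1 kHz steps
  at zero ILD/ITD; ILD sweep −40..40 dB in 1 dB steps at BF; ITD
  (phase-delay) sweep −80..80 µs in 1 µs steps at BF; responses averaged
  over carrier phases and max-normalized.
* **Tuning-curve classes** — monotonic if |Spearman ρ| ≥ 0.9; else
  peaked if a single interior maximum with prominence ≥ 0.3; else cyclic
  if the dominant nonzero Fourier component explains ≥ 50% of variance
  with ≥ 1 full period in range; else flat.  The class criteria are
  explicit stand-ins (the source reports labels, not thresholds); the
  peaked test precedes the cyclic test because a narrow bump's spectrum
  can still be dominated by its first harmonic.
* **Distribution comparison** — KL divergence and Bhattacharyya
  coefficient on shared binnings (2 dB / 5 µs bins for cue histograms;
  additive smoothing 1e-6 where KL needs it).
* **Group statistics** — one-way ANOVA (own pooled-variance formulas,
  equal to the reference implementation to 1e-10) and pairwise Cohen's d
  with pooled std.

## Known limitations

The synthetic HRTF is a designed stand-in: behavioral results under it
demonstrate the mechanism, not bat-specific effect sizes, and the
fraction-of-response-type statistics reported for measured bat HRTFs
are not reproducible without that data.  Scaled-profile training is a
single realization per condition; orderings across roll conditions
carry seed-to-seed variability.  The AR(5) default coefficients are
calibrated, not measured.  No SOFA reader is included; HRTF sets load
from the package's documented HDF5 dialect or are generated.
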