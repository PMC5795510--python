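# Methods

`imu2seg` solves two calibration problems for body-worn inertial sensors
during walking, each from a single two-second window of raw data (128
samples at 60 Hz, accelerometer + gyroscope, no magnetometer):

1. **Assignment** — which of seven lower-body segments (left/right foot,
   lower leg, upper leg, and pelvis) is this IMU mounted on?  A 7-class
   classification problem.
2. **Alignment** — what is the constant rotation `R_SI` between the
   segment's anatomical frame and the sensor frame?  A 3-DoF regression
   problem.

Both are solved per IMU, so the approach scales to any number of sensors.
The sensor position on the segment is assumed fixed at the segment
midpoint; only the mounting orientation is estimated.

## Coordinate frames and transforms

Global frame `G` is z-up.  Segment frames `S` have x anterior and z
longitudinal (pointing proximally) for the legs; feet have x anterior along
the foot and z up.  With `R_GS, S_G` the segment pose and `R_GI, I_G` the
sensor pose,

```
R_SI = (R_GS)^T R_GI          I_S = (R_GS)^T (I_G − S_G)
R_GI = R_GS R_SI              I_G  = R_GS I_S + S_G
```

These four identities are the backbone of the simulator and are tested as
exact (1e-12) round trips.

## Regression target: stereographic quaternion projection

Rotations are regressed as the stereographic projection of the unit
quaternion, `s = (x, y, z) / (1 + w)` for canonical (`w ≥ 0`) quaternions.
The map is minimal (3 parameters), has rational derivatives, no singularity
at the identity, and canonicalization removes the quaternion double cover
so each rotation has a unique target.  The exact inverse
`w = (1 − |s|²)/(1 + |s|²)`, `v = 2s/(1 + |s|²)` decodes network outputs.
An axis-angle target was deliberately not implemented (singular at the
identity, irrational derivatives).

## Alignment-variation augmentation

Recording training data for every possible mounting orientation is
infeasible; instead, variations are synthesized.  Segments are treated as
capsules with the IMU tangent to the surface (sensor z ≈ outward normal),
so the physically plausible mountings form a two-parameter family: a spin
`θ1` about the sensor's own z-axis and a slide `θ2` about the segment's
long axis `a`:

```
R̂_SI(θ1, θ2) = R_a(θ2) · R_SI · R_z(θ1),   θ1, θ2 ∈ {0°, 45°, …, 315°}
```

giving 8 × 8 = 64 variations per segment.  `a` is the segment z-axis for
the four leg segments, the y-axis for the pelvis, and the normalized
forward-and-down vector (0.9, 0, −0.4) for the feet (toward the head of the
second metatarsal projected onto the ground; the printed vector has norm
≈ 0.985 and is normalized because a rotation axis must be unit length).
Tuples are enumerated θ1-major so variation indices are reproducible.

## IMU simulation

From segment poses and a constant `R_SI, I_S`, sensor poses follow from the
transforms above; signals follow by differentiation:

* **Gyroscope**: `ω_I(t) = log(R_GI(t−1)^T R_GI(t+1)) / (2Δt)` — central
  differences through the rotation logarithm, one-sided at the ends,
  O(Δt²) accurate and expressed in the sensor frame.
* **Accelerometer** (specific force): second central differences of `I_G`
  minus gravity `g = (0, 0, −9.81)` m/s², rotated into the sensor frame.
  At rest the output is the +9.81 m/s² gravity reaction regardless of
  attitude — a property tested to 1e-9.

Measurement artifacts, each configurable and skippable:

* **Pose pre-filtering** (for noisy motion-capture input): zero-lag
  Butterworth, order 8, 10 Hz cutoff.  "Order 8" is realized as a
  forward–backward pass of an order-4 design so the *effective* combined
  order is 8 (`effective_order=False` designs order 8 per pass instead).
  Quaternion components are sign-continuity corrected before filtering and
  renormalized after; both orientations and positions are filtered.
  Synthetic gait is analytically smooth, so the default pipeline skips
  this stage.
* **Quantization**: clip to the sensor range and round to the converter
  resolution.  Defaults mimic the wearable hardware class used in gait
  labs: ±160 m/s², ±2000 °/s, 16 bit.
* **Accelerometer noise**: i.i.d. zero-mean Gaussian with σ = 1 m/s²
  (interpreted as a standard deviation; the nominal "σ² = 1 m/s²" is
  dimensionally ambiguous), seeded.  Gyroscope noise is negligible at this
  scale and not added.

The noise exists to blur the "synthetic gap": real accelerometer traces
during walking deviate from rigid-body re-simulation mostly at ground
impacts (soft tissue, clothing).  The closest-of-k noisy re-simulation
error (`rse_opt`) quantifies how well a noisy fan covers a real signal; it
is monotonically non-increasing in k by construction.

## Synthetic gait generator

A seeded procedural stand-in for motion-capture corpora.  Per subject:
stature in [1.55, 1.95] m with segment lengths as standard anthropometric
fractions (thigh 0.245, shank 0.246, foot 0.152, pelvis width 0.191 of
height); cadence 96–126 steps/min; stride length 1.15–1.50 m scaled by
stature; hip amplitude 18–26°, knee peak 55–68°, foot-pitch amplitude
40–55°; pelvis vertical/lateral oscillation 2–4 / 2–5 cm; left–right
asymmetry jitter up to 3%.  These ranges are typical self-selected-speed
adult walking.

Joint angles are truncated Fourier series in the stride phase: hip a pure
sine, knee two non-negative harmonics normalized to the peak, foot pitch a
stride-frequency wave plus a half-amplitude push-off harmonic.  The foot
curve is deliberately *not* renormalized: its summed excursion (~1.4× the
amplitude parameter) gives the feet the largest cycle-average angular
rates, matching walking phenomenology (foot peak angular velocity
≈ 400–600 °/s exceeds shank, thigh and pelvis) — a relative ordering the
test suite asserts.  The right leg runs half a gait cycle out of phase
(plus jitter).  The pelvis travels at `stride length × stride frequency`
along either an elongated oval ("straight": back and forth with smooth
turnarounds inside ~5 m) or a figure-eight inside 5 × 5 m, with
arc-length reparameterization for constant speed.  Forward kinematics
chains pelvis → hips → knees → ankles with exact joint coincidence
(tested < 1e-9 m).

What the generator does **not** model: ground contact and impact
transients, soft-tissue artifact, measured gait curves, pathological or
non-walking motion, inter-subject style variability beyond the parameter
ranges.  A green learning test therefore establishes that the pipeline and
architectures work end to end on structurally realistic periodic
kinematics — not that the reported full-scale real-data accuracies are
reproduced.

## Windowing and splits

Windows of T = 128 samples, hop 16, channels ordered accelerometer x, y, z
then gyroscope x, y, z.  No input standardization is applied — the
networks' batch normalization handles scale.  Each window carries the
segment label, the stereographic alignment target (constant within a
take), subject id, source tag (real/simulated) and variation index.
Splits are leave-one-subject-out; the non-test windows are shuffled 95/5
into train/validation (over windows, seeded — the split population is a
design choice).

## Network architectures

Both tasks share one trunk (all NumPy, explicit backprop, bit-reproducible
under a fixed seed):

1. **Gaussian-noise augmentation** (training only; by default σ = 1 m/s²
   on accelerometer channels of *simulated* windows only, mirroring the
   simulator noise) followed by **input dropout** with keep probability
   0.8 — in that order.  No dropout between recurrent or dense layers.
2. **Temporal convolution stack**: valid padding, stride 1; each layer is
   conv + bias → batch normalization → ReLU.  Batch-norm statistics are
   per feature map over batch and time (the temporal-convolution
   convention for "per-activation" normalization), with running averages
   at inference.
3. **Recurrent stack**: GRU for assignment, LSTM for alignment (the
   cheaper GRU suffices for classification; LSTM behaved best for
   regression).  Standard gate equations; forget bias initialized to 1;
   orthogonal hidden-to-hidden initialization.
4. **Head** on the last hidden state: 7 linear nodes → softmax
   (cross-entropy loss) for assignment; 3 linear nodes (squared error on
   the stereographic vector, batch mean of the component sum) for
   alignment.

Reference (full-scale) configuration: 4 conv layers × 64 maps, kernel 9,
2 recurrent layers × 128 units, Adam lr 1e-3, batch 100, L2 weight 1e-4
(weights only, not biases/batch-norm affine), early stopping on validation
loss with patience 10, best weights restored.  The desk-scale `tiny`
variant used in CPU experiments: 2 conv × 32 maps, 1 recurrent × 64 units,
≤ 30 epochs; the alignment runs use lr 3e-3, which converges within that
epoch budget.  All of this is configurable; the specific numbers are this
package's choices, made once.

Warm starting copies all weights (shape-checked) from a model pre-trained
on a separate simulated corpus before fine-tuning.

## Evaluation

* Assignment: confusion matrix; precision/recall/F1 (standard definitions
  by default; printed-formula variants behind flags, see module docs);
  micro accuracy; and accuracy after merging left/right mirror pairs,
  because single-IMU windows often cannot distinguish the two legs —
  empirically the dominant error mode.
* Alignment: residual rotation `q_true · q_pred⁻¹` decomposed with
  intrinsic XYZ Euler angles (the composition order and the
  intrinsic/extrinsic choice are conventions fixed here; the opposite
  composition is available for sensitivity checks); absolute per-axis
  deviations in [0°, 180°]; min/max/mean/median/MSE plus box-plot
  quartiles and 1.5·IQR whiskers.
* Simulator validation: per-channel Pearson r and RMSE, and the
  closest-noisy-sample RSE described above.

## Numerical and degenerate-input choices

* Quaternions are renormalized and canonicalized on construction
  (tolerance 1e-6 on input norm, exact unit norm after).
* Angular-velocity differentiation rejects frame-to-frame rotations within
  1e-3 rad of a half turn (sign-ambiguous; > 10⁴ °/s at 60 Hz, physically
  impossible for human motion).
* Quantization clips after rounding so saturated samples sit exactly at
  the range limit.
* Signals shorter than one window yield an empty window list with a
  warning; zero-variance channels yield NaN (missing) correlations;
  zero-support classes yield NaN metrics, never 0.
* Euler decomposition at gimbal lock sets the z-angle to 0 and folds the
  residual into the x-angle.
* Training is fully deterministic given a seed: one generator drives
  shuffling, noise and dropout; there is no hidden global RNG state.

## Desk-scale experiment design

The `pipeline` module reproduces the experiment structure of the
full-scale study at CPU scale: a real-data baseline, simulation-only
training, mixed training, and warm-started mixed training, plus a
single-alignment control.  Because no recorded corpus ships with the
package, "real" windows are a second synthetic pass with stronger noise
(σ = 1.3 m/s²), ~1.5 cm sensor-position offsets and ~4° mounting tilts —
a labelled stand-in creating a controllable synthetic gap, not recorded
data.  Desk-scale training subsamples a fixed number of hop-16 windows per
(subject, segment, variation) take so that epochs stay tractable on one
CPU; the subsample count is part of the experiment spec.

## Known limitations

* The NumPy training loop is single-threaded and orders of magnitude
  slower than a GPU framework; full-scale configurations are supported but
  not practical to train here.
* The synthetic gait generator's gap to real walking is itself synthetic;
  conclusions about real-data transfer are qualitative.
* Left/right disambiguation is out of scope by design (windows are
  processed per IMU); merged accuracy is the honest headline metric at
  desk scale.
* Only walking is modeled; the networks have never seen other activities.
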