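# Methods

`movescreen` implements an automatic recognizer for athletic movement-screen
tasks. The chain is: labeled optical marker trajectories → per-segment
simulated inertial (sIMU) channels → athlete-level train/validation/test
split → z-normalized sliding windows → a convolutional-recurrent window
classifier → per-frame label fusion → frame-level evaluation and a
sensor-placement ablation. Because real movement-screen captures of this
kind are not publicly available, the package ships a synthetic
motion-capture generator that reproduces the *structure* of such data and
is used for all shipped experiments.

## Synthetic motion capture

The body is a 13-segment rigid kinematic tree (head, torso, pelvis, and
left/right upper arms, forearms, thighs, shanks, feet) carrying 45 named
markers, at least three non-collinear per segment. The global frame has X
lateral (subject's left), Y anterior, Z up; all segment frames coincide
with it in the neutral standing pose, so "joint angles" are rotations at
each segment's proximal joint expressed in the parent frame.

A movement template is a set of per-joint angle profiles and a root
translation profile, each a sum of Gaussian pulses of the movement phase
`p ∈ [0,1]`: `θ(p) = Σ A·exp(−(p−c)²/2w²)`. Gaussians keep every profile
infinitely differentiable, so angular velocities and accelerations are
well defined everywhere. Mirroring a template is the exact sagittal-plane
reflection: left/right joints swap, rotations about the lateral (X) axis
are kept, rotations about Y and Z and lateral root translation change
sign. Because limb marker clusters are mirror images and midline markers
are sagittal or in L/R pairs, a mirrored template produces exactly the
reflected, identity-permuted marker trajectories (the test suite asserts
bit-level equality).

The default library has 8 movement classes plus null: three mirror pairs —
step-down (SDR/SDL), lunge (LR/LL), T-balance (TBR/TBL) — and two
bilateral tasks — drop jump (DJ) and squat (SQ). The 13 standard screen task codes
are supported as labels throughout. Torso and arm motion in the sided
tasks is deliberately purely sagittal and bilaterally symmetric, so the
left/right information lives entirely in the legs; this is what makes the
sensor-placement ablation scientifically interpretable on synthetic data
(a torso or arm sensor *cannot* separate mirror pairs, a shank sensor
can), mirroring the single-leg structure of real screen tasks.

Trials are sampled at 120 Hz with 0.5 s null (quiet standing) lead-in and
lead-out around the movement. Defaults chosen as realistic capture
conditions: isotropic marker noise 2 mm (a typical optical residual),
postural sway 4 mm at 0.2–0.45 Hz during standing, per-athlete amplitude
and timing scale factors `1 + N(0, 0.10)` and `1 + N(0, 0.08)` clipped to
[0.7, 1.3]. All randomness flows through one seeded generator per call;
identical arguments give bit-identical cohorts.

What the generator does **not** emulate: soft-tissue artifact, marker
occlusion/relabeling, ground contact dynamics, anthropometric variation in
segment lengths, or within-athlete trial-to-trial strategy changes.
Passing tests therefore show that the pipeline recovers structure that is
present and separable by construction — they bound implementation error,
not real-world accuracy.

## Simulated inertial channels

Each segment's pose series is obtained by a least-squares rigid fit
(Kabsch/SVD with the proper-rotation correction) from the model's
reference cluster to the observed markers, vectorized over frames; on
noise-free rigid data the fit is exact to <1e-10 m. A collinear reference
cluster raises an error (the rotation would be underdetermined). An
independent quaternion-eigendecomposition (absolute-orientation) solver in
the tests confirms the optimum.

From each pose series five channels are derived per segment:

* **Euler angles** (3): global orientation decomposed in a fixed extrinsic
  X-Y-Z Cardan sequence, `R = Rz(γ)Ry(β)Rx(α)`, β ∈ [−π/2, π/2]. The
  sequence is a documented convention, not an inference — any fixed choice
  preserves class separability. At the |β| = π/2 singularity the third
  angle is set to zero, the remaining freedom folds into the first angle,
  and the frame is flagged.
* **‖ω‖** (1): angular velocity from central differences of R via the
  skew part of `Ṙ Rᵀ` (one-sided at endpoints).
* **‖a‖** (1): linear acceleration of the segment COM by second central
  differences (endpoint values mirrored). The COM is approximated by the
  segment's marker centroid; the centroid's acceleration norm carries the
  same signal structure as an anthropometric COM without requiring a body
  model.

ω and a are low-pass filtered **component-wise** with a zero-lag
(forward–backward) second-order Butterworth filter, 15 Hz cutoff at
120 Hz, and the Euclidean norm is taken afterwards. Filtering the scalar
norm directly was rejected: a norm is non-smooth at zero and the filter
undershoots below zero at movement transients, violating the
non-negativity of the channel. Component-wise filtering commutes with any
fixed global rotation, so the norms remain orientation-invariant — the
design rationale for using norms in the first place (robustness to sensor
alignment). Euler angles are left unfiltered. Derivatives and filtering
are always computed per trial, never across concatenation seams.

Sensor subsets follow the standard nine configurations (sIMU1 = torso …
sIMU13 = all segments), each with 5 × (number of segments) channels;
bilateral entries expand to left + right.

## Dataset construction

Splits are by **athlete**, never by trial: `floor(2n/3)` training, the
remainder halved (floor to validation, ceil to test), after a seeded
shuffle — at n = 417 this yields 278/69/70. Channels are z-normalized
with the mean and standard deviation of all *training* frames pooled
across athletes and movements; standard deviations are floored at 1e-8 so
constant channels normalize to zero. Statistics are refit for every
channel subset trained (each sensor configuration is an independent
experiment) and are never recomputed on validation or test data.

Sliding windows of SWS frames advance by SWS/4; trailing frames that do
not fill a window are dropped (frame fusion restores coverage at test
time). Each window takes the majority frame label; ties prefer a movement
class over null, then the label occurring earliest in the window — a
deterministic rule that favors movement recall.

## Classifier

The network is the DeepConvLSTM shape used for wearable activity
recognition: four valid (no-padding) temporal convolutions with ReLU, two
stacked LSTM layers, a linear layer on the last time step, and a softmax.
The temporal length after the convolutions is `SWS − 4(k−1)`, which must
stay ≥ 1; infeasible combinations (e.g. window 24 with kernel 8) are
rejected at configuration time. Implementation choices: uniform
`±1/√fan_in` initialization, forget-gate bias 1, float32 parameters with
a float64 softmax for numerical stability, no pooling, dropout available
but off by default, no weight decay or schedule.

The forward pass, backpropagation through time and the SGD-with-momentum
optimizer (`v ← μv + g`, `θ ← θ − ηv`) are implemented directly on numpy
arrays; the test suite verifies the analytic gradients against central
finite differences to 1e-6 and checks overfitting to certainty on a small
separable set. Training is mini-batch (batch 100 by default) with seeded
shuffling; the validation metric is window-level micro-averaged F1
(equal to accuracy for single-label prediction), early stopping keeps the
best-validation parameters with a default patience of 10 epochs. A
non-finite loss aborts with a diagnostic rather than silently diverging.

## Evaluation

At test time the classifier is applied per athlete: all the athlete's
trials are concatenated, windowed, and classified; then each frame's class
distribution is the arithmetic mean of the probabilities of every window
containing it, and the frame label is the argmax (ties to the lowest
class index). Frames not covered by any window — possible at the trailing
edge — inherit the nearest covered frame's distribution, so every frame is
scored. Confusion matrices are accumulated per athlete and summed;
per-class precision/recall/F1 (0/0 defined as 0), micro averages (pooled
— identical to accuracy) and macro averages (unweighted class means) are
derived from the summed counts. The left/right confusion rate of a run is
the fraction of mirror-pair-class frames predicted as the partner task.

Hyperparameter tuning is two-stage: learning rate × momentum
({1e-4…1} × {0.5…0.98}, 25 points) on a fixed architecture first, then
window size/kernel (24→{5,6}, 48→{6,8}), convolution channels
{32, 64, 96} and LSTM cells {64, 128, 192} (36 points) with the winning
learning parameters. Selection uses window-level validation micro-F1 —
the quantity available during training, before fusion is introduced;
final reported numbers are always frame-level after fusion. Ties break
toward the lower learning rate/momentum, or the smaller model.

## The shipped end-to-end experiment

The desk-scale experiment (`movescreen.pipeline.synthetic_e2e_config`,
also run by `scripts/acceptance.py`) uses a 24-athlete cohort (16/4/4
split) over the 8-class default library, ~2 880 frames per athlete, and a
compact network — window 24, kernel 5, 16 convolution channels, 32 LSTM
cells, learning rate 0.02, momentum 0.9, batch 100, ≤100 epochs with
patience 12 — sized so each sensor configuration trains in about a minute
on one CPU while leaving ample headroom above the recovery thresholds.
Typical results (seed 1): micro-F1 ≈ 0.96 for the full-body configuration,
≈ 0.91 for torso+shanks, ≈ 0.67 for torso+upper-arms and ≈ 0.53 for torso
only, with left/right confusion rates of ≈ 0.30 (torso only) and ≈ 0.46
(torso+arms) versus ≈ 0.002 (torso+shanks) — the qualitative ordering
expected when lateral information lives in the legs.

## Known limitations

* The synthetic cohort is far easier than real data: absolute scores have
  no external meaning; only orderings and recovery-from-structure do.
* The marker-centroid COM is not an anthropometric COM; absolute
  acceleration magnitudes differ from what a body-model pipeline reports.
* Real IMU error sources (bias drift, noise spectra, mounting
  misalignment) are out of scope by design.
* The Euler-angle channels depend on the chosen Cardan sequence;
  orientation-sensitive downstream analyses should treat them as
  convention-bound quantities.
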