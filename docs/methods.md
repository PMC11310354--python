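# Methods

This note documents the models, algorithms, and numerical choices behind
strainkit: what is computed, under which assumptions, and why the open
design decisions were resolved the way they were.

## Problem setting

A tendon imaged with B-mode ultrasound during a contraction cycle yields
a sequence of grayscale frames (I_t), t = 1..T. The goal is the dense
2-D strain field of every frame relative to the first — the symmetric
tensor with longitudinal (ε_xx), transverse (ε_yy), and shear (ε_xy)
components at each pixel. Classical texture-correlation methods (DIC,
DDE) solve this by subset matching and degrade sharply at the low
signal-to-noise ratios typical of in-vivo imaging; the two-stage
convolutional pipeline implemented here is trained on synthetic pairs
with exact ground truth so that it learns to see through those
artifacts.

Array convention throughout: axis 0 is depth (y, superficial tissue at
low row indices), axis 1 is longitudinal (x); origin top-left, 0-based,
pixel units. Strains are dimensionless; a "5% strain" is 0.05.

## Synthetic data engine

### Tendon deformation model

The prescribed deformation encodes two empirical observations about
tendon under load:

1. **Depth grading.** The longitudinal strain at the superficial tendon
   edge is a fixed fraction (default 0.75) of the strain at the deep
   edge. ε_xx ramps linearly across the tendon thickness between those
   two endpoints and is constant along the tendon axis. Outside the
   tendon, strain decays to zero with a raised-cosine taper over a
   margin of 10% of the image height — a taper rather than a cutoff
   because a discontinuity at the tendon boundary produces spurious
   boundary error in every estimator.
2. **In-plane incompressibility.** Area preservation in the stretch-ratio
   form (1 + ε_xx)(1 + ε_yy) = 1 couples the transverse strain to the
   longitudinal one: ε_yy = 1/(1 + ε_xx) − 1. This holds pointwise to
   1e-9 in every generated field.

A depth-graded ε_xx is not kinematically compatible with exactly zero
shear: integrating u(x, y) = ∫ ε_xx dx gives ∂u/∂y ≠ 0 wherever ε_xx
varies with depth. The stored ground truth therefore keeps the closed
forms for ε_xx and ε_yy (so the ratio and incompressibility invariants
are exact) and records the induced shear ½(∂u/∂y + ∂v/∂x) computed from
the same displacement used to warp the image. This makes the truth
consistent with what an ideal estimator would measure from the images
(verified by the round-trip and DIC cross-checks in the test suite).

Displacements are obtained by cumulative trapezoidal integration of the
strain components from an anchor at the image center.

### Image synthesis

Real B-mode substrates are replaced by procedural speckle: band-limited
Gaussian texture (autocorrelation length ≈ 2-6 px, matching the
granularity that subset matching relies on) plus a brighter horizontal
band emulating the hyperechoic tendon. Any user-supplied grayscale
image can substitute for the procedural substrate.

Warping is exact rather than approximate: for each output pixel x the
reference position X solving X + u(X) = x is found by fixed-point
iteration, then the substrate is sampled there with bicubic
interpolation (edge replication outside the domain). Naively sampling
at x − u(x) would bias the realized strain by a factor ≈ 1/(1 − ε) —
almost 3% absolute at the 16% benchmark level — which would corrupt
every downstream accuracy number.

### Noise model

Ultrasound-like corruption is applied independently to each frame, in
order: a unit-mean gamma-distributed multiplicative factor (speckle
decorrelation), additive Gaussian noise (sensor noise), and a global
gain/offset jitter (insonation variability); the result is clipped to
[0, 1]. Every component's strength is drawn uniformly from a
configurable range, so a dataset spans a spectrum of noise severities.
Defaults: speckle variance (0, 0.08), additive σ (0, 0.04), gain
(0.9, 1.1), offset (−0.03, 0.03). These were fixed before any
end-to-end runs and sanity-checked only against the reported difficulty
of classical methods: under these ranges DIC's median strain error on
the noisy 10% benchmark case is ≈ 6%, within the 5-10% band reported
for subset methods on comparable data. `NoiseParams.scaled(f)` shrinks
every range about its neutral value; the "noise-reduced" benchmark used
in the scaled-down accuracy study is `scaled(0.25)`.

What the generator does **not** emulate: RF-domain speckle physics
(interference, attenuation, shadowing), out-of-plane motion, probe
pressure artifacts, and anatomical heterogeneity. Passing the desk-scale
study therefore demonstrates the pipeline's correctness and its noise
robustness **relative to the modeled artifacts**, not clinical-grade
performance on real images.

### Training set and benchmark cases

Training pairs (default 3750 at full scale; 300 in the tiny study) are
drawn per sample: a class from (tension, compression, rigid) with equal
default proportions, then a deep-layer strain magnitude uniform in
[0.02, 0.20] for the strained classes or a uniform translation in
[−5, 5] px per axis for the rigid class, a fresh speckle substrate,
exact warping, and independent noise on both frames. The 2% lower
magnitude bound exists because the class label must be decidable from
the images: at 64 px a 10⁻³ strain moves the fastest pixel by ~0.03 px
and is indistinguishable from rigid motion, so sampling strains down to
zero would put a hard floor under the achievable classification
accuracy. Both bounds are configuration, not constants.

Benchmark cases prescribe a ramp-hold-relax load profile (3 s / 5 s /
3 s, piecewise linear in time) scaled to peak deep-layer strains of
4, 7, 10, 13, and 16%, sampled at 2 frames/s (23 frames per case —
enough to resolve every phase of the 11 s cycle while keeping
five-case × three-method evaluations affordable on one CPU core).
Ground truth is stored per frame relative to frame 1, before noise.

## The two-stage network

Stage 1, the deformation classifier, labels a frame pair as tension,
compression, or rigid motion: conv(3×3)/batch-norm/ReLU blocks with 2×2
max pooling (widths 8-16-32-64 in the tiny profile), then two fully
connected layers to 3 logits. Stage 2 routes the same pair to one of
three independent UNet-style regressors (one per class): a
double-conv encoder with pooling, a decoder with nearest-neighbor
upsampling and skip concatenations, and a linear 3×3 output head
predicting (ε_xx, ε_xy, ε_yy) at input resolution. Nearest-neighbor
upsampling avoids checkerboard artifacts; the final layer has no
activation so strains may be negative; the three regressors share no
weights.

**Regressor input featurization.** At a few hundred training samples a
small CNN fed the raw pixel pair does not learn correspondence — it
converges to predicting the class-conditional *mean* strain field
(response slope ≈ 0.3 against the true magnitude in our measurements,
and even a dedicated convolutional scalar regressor failed to recover
the deformation amplitude). The regressors therefore receive a fixed,
deterministic correspondence featurization alongside the two frames,
in the spirit of the cost volumes used by optical-flow networks: a
smoothed-SSD cost volume over integer longitudinal shifts (±6 px, the
displacement range of the deformation model at 64 px), soft-argmin
displacement maps of the longitudinal and transverse cost volumes,
Lucas-Kanade-style linearized sub-pixel displacement estimates, and
smoothed spatial gradients of those displacement maps — i.e. direct,
noisy strain estimates that the UNet refines, denoises, and fuses.
This restores a near-unit response slope at desk scale. The UNet
topology itself is unchanged, and a `features="raw"` mode reproduces
the plain stacked-pair input; the choice is stored in every
checkpoint.

All networks run on a small numpy layer stack written for this package
(`strainkit.nn`) with manual backpropagation, verified against
central-difference numerical gradients to 1e-6 relative error. Forward
passes in evaluation mode are deterministic, and initialization is
reproducible from a seed.

Input normalization is per-image: min-max to [0, 1] for the regressors,
z-score standardization for the classifier. The difference is
deliberate — min-max is dominated by single extreme pixels under
heavy-tailed multiplicative noise, and the classification task (sub-pixel
motion-pattern discrimination) proved markedly more sensitive to that
than the regression task.

## Training

Losses follow the two-stage split: cross-entropy over the three classes
for the classifier (probabilities clipped at 1e-12 before the log), and
for each regressor the mean squared strain-tensor error over examples
and pixels, with the tensor expanded as ε_yx = ε_xy so the **shear
component is counted twice**. A "3-channel MSE" would weight shear
equally and produce different loss values; the double-sum form is what
the loss oracles in the test suite check against.

The dataset is split 80/20 into training and validation, stratified by
class (guaranteeing all classes in both splits even at small n).
Optimization is Adam. The full-scale recipe (100 epochs, lr 1e-3,
batch 100 classifier / 10 regressor) is the configuration default; the
**tiny profile** actually exercised trains 64×64 networks on ~300 pairs
for 30 epochs and adds four things that the low-sample regime needs:

* the regressor output head is initialized near zero, so training
  starts from an almost-zero strain prediction and learns the field as
  a residual (without this the desk-scale regressors underfit to the
  point of being worse than a zero predictor);
* BatchNorm running statistics are re-estimated on a training batch
  after each epoch — with only a few hundred optimizer steps the
  exponential running averages otherwise lag far behind the weights,
  corrupting evaluation-mode predictions;
* the learning rate follows a cosine decay, and the regressors use a
  base rate of 3e-3 (the classifier keeps 1e-3 with batch 8);
* per subnetwork, the retained checkpoint is the validation-loss
  minimum for the regressors and the validation-accuracy maximum (ties
  to lower loss) for the classifier.

Training is fully seeded and reproducible; a rerun with the same seed
reproduces the final validation metrics exactly.

## Inference

Each pair is classified and routed to the matching regressor; frames are
reflect-padded to the regressor's resolution multiple and cropped back.
Two pairing modes exist because strain relative to the first frame and
frame-to-frame pairing are both defensible readings of the protocol:
`reference` (default) feeds (I_1, I_t) and outputs cumulative strain
directly; `incremental` feeds (I_t, I_t+1) and composes steps by
multiplying per-axis stretch ratios ((1+E)(1+e) − 1) and adding shear —
a small-strain approximation of composing deformation gradients, exact
for the diagonal in 1-D and in error only at O(ε²) cross terms.

## Baselines

**DIC** (subset digital image correlation): odd-sized square subsets on
a regular grid; integer normalized-cross-correlation search (subsets
with NCC peak below 0.5, or zero variance, are marked invalid — not
errors); Gauss-Newton refinement of a 6-parameter affine (linear shape
function) on the SSD of bicubic-interpolated intensities (tolerance
1e-4 px, ≤ 50 iterations); strain at each center from least-squares
plane fits of the displacement over its 3×3 neighbor centers.

**DDE** (direct deformation estimation): identical matching, but strain
is read directly from the gradient part F of the converged affine,
ε = ½(F + Fᵀ) − I, with no displacement differentiation.

Both produce dense fields by linear interpolation of per-center values,
valid only inside the convex hull of converged centers — hence always a
strictly smaller valid region than the network's full-field output.
Hyperparameters can be grid-searched (subset ∈ {21, 31, 41},
step ∈ {4, 8, 16}) against a held-out case with known truth
(`tune_grid`); defaults are subset 21, step 8.

## Error metrics and comparison

Per pixel, the spatial strain error is the Frobenius norm of the tensor
difference, √(Σ_ij (ε̂_ij − ε_ij)²) with the off-diagonal counted twice.
The per-frame error is its median over the overlap region (the pixels
where all compared methods returned a valid estimate); the cycle-level
error pools all overlap pixels of all frames and takes one median
(pooled, **not** a median of per-frame medians). For multi-method
comparisons the overlap is taken per frame and pixels pooled across
frames, since under heavy noise the all-frame conjunction of subset
validity masks can be empty.

Method pairs are compared with a two-sided permutation test on the
difference of sample medians (add-one estimator, default 10,000
permutations, seeded; internally the pooled sample is sorted and the
smaller group placed first so the p-value is exactly invariant to
swapping the inputs). Caveat stated once and plainly: pixels within a
frame are spatially correlated, so pixel-level permutation overstates
the effective sample size; the test is reported in this form for
comparability, and frame-level pooling is available by passing
per-frame medians instead of pixel samples.

## Tendon mechanics

Bulk longitudinal strain of a trial is the pooled median of ε_xx over
tendon pixels and hold-phase frames (default hold window [ramp,
ramp+hold] = [3 s, 8 s]). Grip force maps to tendon force with a
configurable linear transmission coefficient (default 0.25 — a
placeholder scalar standing in for a subject-specific biomechanical
relation, not an anatomical claim); stress is tendon force over the
undeformed cross-sectional area (N/mm² = MPa). The apparent modulus is
the slope of the most linear stretch of the loading-phase stress-strain
curve: every contiguous window covering ≥ 40% (configurable) of the
loading points is fit by OLS and the window with the highest R² wins
(ties prefer longer windows). The loading phase is the protocol's ramp
— the frames where stress actually increases — extended through the
hold only when fewer than five ramp frames exist; on short trials a
larger window fraction (0.8 in the shipped round-trip study) keeps the
max-R² selection from chasing frame noise. Effort-response relationships use OLS with subject as a fixed
blocking term when more than one subject is present.

## Problem sizes of the shipped study

The repository's tests and the acceptance script run the tiny profile:
64×64 px frames, 300 training pairs, 30 epochs, the five benchmark
cases at 2 frames/s with quarter-strength noise for the accuracy study
and full-strength noise for the method comparison. These sizes are the
package's desk-scale study design; the full-scale recipe remains
available through `TrainingConfig` defaults and the YAML configuration.

## Known limitations

* The speckle substrate and noise model are statistical proxies; none of
  the RF-domain physics of ultrasound is simulated.
* Only three bulk deformation modes are modeled; mixed or rotational
  motion falls outside the class set.
* The incremental composition ignores O(ε²) shear/normal coupling.
* The permutation test treats pixels as exchangeable units despite
  spatial correlation (see above).
* The grip-to-tendon transmission is a single configurable scalar.
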