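# Methods

## The problem and the two-stage approach

Metal implants corrupt kilovoltage (kV) CT with streaks, dark bands and
value bias: rays crossing high-Z material are beam-hardened and
photon-starved, and filtered back-projection (FBP) spreads the corrupted
projections across the slice. Supervised artifact correction needs
(contaminated, artifact-free) image pairs, which do not exist clinically —
there is no artifact-free kV scan of a patient with an implant.

The framework implemented here manufactures those pairs from a second
modality. Megavoltage (MV) CT is nearly insensitive to metal artifacts
(the photoelectric effect, which drives metal's excess attenuation at kV
energies, vanishes at MV energies), at the cost of much lower soft-tissue
contrast and more noise. Two generative adversarial translators are trained
in sequence:

1. **Stage 1 (modality translation).** A generator maps registered MV
   slices to synthetic kV slices. It is trained only on slice pairs whose
   true kV maximum is ≤ 3000 HU (metal-free by the HU rule), because metal
   slices contain artifacts in the kV target that the translator would
   learn to reproduce. At inference stage 1 is applied to *every* slice,
   including the withheld ones.
2. **Post-processing.** The synthetic kV cannot depict implants (it never
   saw them in training), so voxels where the measured kV exceeds 3000 HU
   are copied from the measured kV into the synthetic volume (*intensity
   override* — the implant, not its artifacts, is restored). A mono-modal
   deformable registration (MSE metric) then warps the overridden synthetic
   volume onto the measured kV to absorb residual misalignment left by the
   earlier multi-modal registration.
3. **Stage 2 (artifact correction).** A second generator is trained with
   the measured (contaminated) kV as input and the refined synthetic kV as
   target, using only studies that contain metal slices. After training,
   stage 2 is the *only* network applied to new data.

## Loss

Both stages use the same generator objective

    L = L_adv + λ · [ (1/N) Σ_i |G(M_i) − K_i|  +  (1 − SSIM(G(M), K)) ]

with λ = 10. `L_adv` is the conventional non-saturating GAN binary
cross-entropy (a least-squares variant is available behind a flag). SSIM is

    SSIM(x,y) = (2 μ_x μ_y + c1)(2 σ_xy + c2) /
                ((μ_x² + μ_y² + c1)(σ_x² + σ_y² + c2))

computed as the mean of local Gaussian-windowed statistics (11×11 window,
σ = 1.5, K1 = 0.01, K2 = 0.03 over the data range 2 of [−1, 1]-normalized
images). A single-window "global" mode, evaluating the formula once with
whole-image moments, exists for closed-form verification. The single-window
form printed as a formula is insensitive to local structure on full slices,
which is why the windowed form is the default. The λ weight multiplies the
bracket [L1 + (1 − SSIM)] jointly.

## Architectures

Generator: 7×7 stem convolution → three stride-2 down-sampling blocks (4×4
kernels, channel width doubling) → eight residual blocks (3×3, identity
shortcuts) → three transposed-convolution up-sampling blocks → 7×7 head →
tanh. Instance normalization and ReLU throughout. There are **no**
encoder–decoder skip connections: a skip path copies input streaks directly
into the output, defeating artifact removal. Discriminator: five stride-2
convolution blocks (leaky ReLU, instance norm after the first), a 1-channel
head, global average, sigmoid — one realness score in (0, 1) per image
(a patch-wise head is a config flag, default off).

Full-scale base width is 64 channels; the desk-scale preset uses 16.
Input sides must be divisible by 2^3; violations raise at call time.

## Training

Adam (lr 2·10⁻⁴, β₁ = 0.5, β₂ = 0.999), mini-batch 3, constant learning
rate, 100 epochs at full scale (10 in the desk preset). Per batch: one
discriminator step (detached fake), then one generator step. Augmentation
applies the *same* sampled left-right flip, rotation in ±10°, and integer
translation in ±20 voxels to both images of a pair; one augmented copy per
original for stage 1 ("doubling"), two for stage 2 ("tripling"); at desk
scale translations beyond the 64 px field are harmless because padding is
−1000 HU (air). Splits are by study: stage-1 validation studies never feed
stage-2 training, and a held-out pool (default 20%) is touched only by the
final evaluation. The checkpoint with the best validation SSIM is returned;
all epochs' metrics are logged to CSV so the choice is auditable.

The networks run on a small numpy reverse-mode autodiff engine written for
this package (`martian.nn`): im2col convolutions, a transposed-convolution
adjoint, fused instance norm, Adam. Gradients of every primitive are
verified against central finite differences in the test suite. Compute is
float32 (float64 in the gradient-check tests); training is deterministic
for a fixed seed and thread count.

## Registration

`martian.registration` wraps SimpleITK: optional rigid (Euler2D) stage,
then cubic B-spline FFD, three-level multiresolution (shrink 4/2/1),
full-sampling metrics for determinism — Mattes mutual information (32 bins)
for MV↔kV, mean squares for mono-modal refinement. Displacement fields are
dense per-pixel vectors on the fixed grid; warping is pull-back linear
interpolation with −1000 HU fill. A fixed-point numerical field inverse
supports round-trip testing. Degenerate (constant) inputs return identity
with a warning rather than failing.

Default B-spline control spacing is 64/32/16 mm per level, appropriate for
a ~250 mm clinical head on a 512 grid. Control spacing must resolve the
deformation actually present — the finest level needs control points
denser than the warp's correlation length, or the transform cannot
represent it regardless of optimizer effort. The desk preset therefore
scales the *refinement* spacing to 16/8/4 mm (its phantom field of view is
only 64 mm — the same proportional freedom), and the warp-recovery tests
pass 32/16/8 mm for their ~10 px-correlation synthetic fields. Metric traces are recorded with
level boundaries; values are only comparable within one level.

## Synthetic paired-modality generator

The fixture stands in for the kind of radiotherapy cohort this method is
built for, in which roughly four of five scans contain metal-bearing
slices — hence the default `metal_fraction` 0.8 of studies containing at
least one metal slice. Each study is one "patient":
an elliptical head section with a skull rim, 1–2 bone blobs, an optional
air cavity, and (in metal studies) 1–2 circular implants of 3200–6000 HU.
Anatomy — shapes *and* tissue intensities (skull HU, soft-tissue baseline)
— is drawn per study; slices jitter it slightly, emulating adjacent
cross-sections of one person. Soft tissue gets a Gaussian-smoothed random
texture within ±20 HU of the study baseline.

Three channels per study:

* `kv_clean` — the rendered ideal image (ground truth; never passed
  through any corruption),
* `kv_artifact` — the "measured" kV: slices with metal and a severe-artifact
  draw (75% of metal slices) go through HU→attenuation (linear map, water
  0.0206 per pixel), parallel-beam radon (180 angles full scale, 90 desk),
  a quadratic beam-hardening deficit, Gaussian noise, and photon-starvation
  saturation applied *only* to sinogram bins whose rays cross metal
  (the metal trace, found by forward-projecting the metal mask), then ramp
  FBP and attenuation→HU. Metal pixels are reinserted afterwards so the
  implant reads bright, as it does clinically. The remaining 25% of metal
  slices model dense objects without severe artifacts — the evaluation
  subcategory the study design needs. With severity 0 the output is exactly
  the FBP round trip of the input, which is the measured error bound the
  tests use.
* `mv_like` — positive HU (soft tissue, bone) scaled toward water by 0.35,
  metal retained unscaled and streak-free, 25 HU Gaussian noise, then a
  known smooth random deformation (~2.5 px) recorded as ground truth for
  the registration stage.

What the fixture does **not** model: polyenergetic spectra, scatter,
detector physics, fan/cone geometry, real anatomical variability. Passing
tests therefore demonstrate that the pipeline's machinery — exclusion
rules, translation, override, refinement, adversarial training — behaves
as designed on controllable artifact phenomenology; they are not evidence
of clinical performance.

## Evaluation

MAE is reported in HU, optionally masked. Evaluation-space SSIM windows
both images to a display range (default [−1000, 1500] HU, the soft-tissue
window of the figures in this literature) before applying the loss-module
SSIM, making it invariant to joint affine rescaling. Slices are bucketed
metal_free / metal_containing by the truth volume's max HU (threshold
3000, configurable since the source material is inconsistent between 3000
and 4000 for the high-density evaluation); the
"high-density, no severe artifact" subcategory requires caller-supplied
flags — clinically that judgement was visual, and the synthetic manifest
records it.

## Desk-scale study conditions

The acceptance-grade end-to-end run uses 48 studies of 3 slices at 64×64
px, 16 base channels, 10 epochs per stage, 90 projection angles, and 20
registration iterations per level — sized so a full run fits in minutes on
one CPU. At these conditions the no-skip translator's reproduction error
after 10 epochs is of order 100 HU — far from the clinical-scale training
regime (100 epochs × thousands of 512² slices) — which bounds what the stage-2
output can achieve against the clean ground truth; the report's monotone
SSIM ordering (MV < stage-1 < post-processed) is the robust signature of
the chain at this scale. Seeded reruns reproduce reports exactly; the
rerun-determinism test uses a reduced cohort so two full runs fit the
suite's time budget.

## Numerical choices and edge cases

* Normalization window [−1024, 3071] HU mapped affinely to [−1, 1];
  out-of-window values clip; the inverse is exact within float error.
* HU→attenuation clips at zero (no negative attenuation).
* Adversarial scores are clamped to [10⁻⁷, 1 − 10⁻⁷] before logs.
* SSIM on images smaller than the 11×11 window raises and points to the
  global mode.
* Overlapping metal and air shapes, disjoint resampling grids, empty masks,
  non-finite sinograms, and unnormalized training pairs all fail loudly.
* Ties in best-validation-SSIM checkpointing resolve to the later epoch.
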