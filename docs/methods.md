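# Methods

## Problem and model

`mmdda` implements a multi-modal deep domain-adaptation classifier for
binary staging of Alzheimer's disease from paired, co-registered 3-D brain
volumes: a structural MRI channel (atrophy) and an FDG-PET channel (glucose
metabolism).  Two cohorts are involved: a **source** domain with diagnostic
labels and a **target** domain without them, whose acquisition differs
enough that a source-trained classifier degrades on it (domain shift).  The
model learns features that are simultaneously class-discriminative and
domain-invariant, so the source-trained classifier transfers to the target
cohort without target labels.

The pipeline has three stages.

**Feature encoding.**  Four parallel 3-D CNN branches (MRI/PET x
source/target).  Each branch is nine 3x3x3 valid convolutions (stride 1, no
padding) with channel widths 8, 8, 16, 16, 32, 32, 64, 64, 128, each
followed by batch normalisation and leaky ReLU (negative slope 0.01, the
conventional default; the reference description does not state it), with
2x2x2 stride-2 max pooling after layers 2, 4, 6 and 8.  On the full-size
113 x 137 x 113 input the spatial trace ends at (1, 2, 1); the module
computes this trace analytically and validates every input against it.

**Attention fusion.**  The MRI and PET feature maps are concatenated along
channels and reshaped to a sequence of L = D·H·W positions with E = 2C
features; one application of multi-head scaled dot-product attention
(square E x E projections, no bias, no positional encoding, h heads with
d_k = E/h) mixes the sequence, and the output is reduced over the sequence
axis to the fused per-subject vector F of dimension d.

*Interpretive choice*: with the full-size encoder the attention output is
(L=2, E=256) and a raw flatten would give 512 dimensions, inconsistent with
the stated fused dimension d = 256.  We reduce over L by arithmetic mean,
the only reading consistent with d = E = 256; `fusion.reduce = "flatten"`
is kept for sensitivity checks.  Default head counts per task follow the
reference configuration: 4 (AD vs CN), 4 (MCI vs CN), 8 (AD vs MCI),
16 (pMCI vs sMCI).

**Adversarial domain transfer.**  A category classifier C_S and a domain
discriminator C_D, both 128-64-2 fully connected stacks with dropout 0.5
after the hidden layers (placement after both hidden layers is our choice;
only the rate is specified) and softmax outputs.  C_D sits behind a
gradient-reversal layer: identity forward, gradient times -lambda
(lambda = 0.1, constant) backward, so the encoder/fusion path ascends the
domain loss the discriminator descends.

## Objective

With flattened per-modality encoder features x_i (MRI) and x_j (PET) of a
batch, the Gaussian-kernel cross-modal correlation loss is

    K(x_i, x_j) = exp(-||x_i - x_j||^2 / (2 sigma^2)),      sigma = 1
    L_cor       = - sum_i sum_j K(x_i, x_j) log(K(x_i, x_j) + 1e-6)

computed within the source batch (L_cor^S) and the target batch (L_cor^T).
The consistency loss L_mse is the mean squared difference between the
source and target fused vectors; L_cls and L_dom are mean cross-entropies
of the class and domain predictions (natural logarithm).  The total
objective is the unweighted sum

    L_total = L_cor^S + L_cor^T + L_mse + L_cls + L_dom.

Config hooks expose per-component weights (default 1.0); the ablation
variants zero specific terms.

Two structural properties of L_cor are worth noting, and are covered by
tests rather than altered:

* for a single pair, -K log(K + eps) vanishes both as K -> 1 and K -> 0,
  with a maximum near K = 1/e, so the loss penalises *intermediate*
  similarity rather than strictly forcing alignment;
* for high-dimensional, weakly-matched features the squared distance is
  large, K underflows to zero, and the term contributes neither value nor
  gradient.  The loss is implemented exactly as defined.

Cross-entropy inputs are clamped at 1e-12 before the logarithm so saturated
softmax outputs stay finite; this perturbs values far below any reported
precision.

## Training protocol

Two phases with one Adam optimizer (betas 0.9/0.999, learning rate 9e-7,
batch size 1) spanning both: reference schedule 150 epochs of source-only
training (L_cor^S + L_cls), then the source weights are copied into the
target branches, then 50 epochs of joint training on the full objective
with the reversal layer active.  Target labels are never read; scrambling
them leaves the trajectory bit-identical (tested).

Unstated details resolved as follows:

* **L_mse pairing** — at batch size 1 the current source sample is paired
  with a cycling target sample (shuffled each epoch).
* **Epoch definition** — one pass over the source samples (phase 1); one
  pass over the longer of the two sample lists with the shorter cycled
  (phase 2).
* **Batch norm at batch size 1** — normalisation over (batch, D, H, W) per
  channel is well-defined for spatial sizes > 1; running statistics are
  kept so eval-mode inference is deterministic.  Whether target-branch
  statistics are frozen in phase 2 is exposed as
  `train.freeze_target_bn` (default: not frozen).
* **Checkpoint selection** — none; the final epoch is used.  The validation
  split exists for head-count/configuration selection only.
* **Initialisation** — seeded Kaiming fan-in normal for all weights, zero
  biases.
* Per-epoch randomness (sample order, dropout masks) derives from
  (seed, phase, epoch), which makes checkpoint-resume trajectories
  identical to uninterrupted ones.

Ablation variants share the protocol and differ only in the active
pipeline: `SDA` (MRI only, flattened features), `MSDA` (MRI+PET, plain
concatenation), `M3HF` (attention fusion, correlation weights zero),
`MMDDA` (full model).

## Evaluation

Confusion counts at decision threshold 0.5 on the positive-class
probability; ACC, SEN, SPE, F1 by their standard formulas, with
zero-denominator metrics reported as undefined (never coerced to 0); AUC as
the rank statistic (ties count one half), cross-checked in tests against a
trapezoidal ROC oracle.  The subject-level split holds out round(0.30 n) as
test, then round(0.30 of the remainder) as validation, stratified by label
and deterministic in (manifest, seed).

## Synthetic data

Real volumes are access-restricted, so the package ships a seeded generator
that emulates exactly the properties the model exploits:

* **class signal** — four Gaussian blobs at fixed canonical positions
  (width 0.12 x volume edge) whose amplitudes differ between classes by
  `class_effect` in alternating directions, so classes are separated by a
  spatial pattern rather than overall brightness; `modality_balance`
  splits the effect between the channels (0.5 symmetric; larger values
  make the PET channel the more class-sensitive one, mimicking FDG-PET's
  higher sensitivity in early disease);
* **modality coupling** — per-subject blob amplitudes mix a shared latent
  with modality-private variation, weighted by `modality_correlation`;
* **domain shift** — target volumes are scaled by `shift_gain`, blurred
  with a Gaussian of width `shift_smooth` voxels, and modulated by a
  seeded order-2 polynomial bias field of relative amplitude
  `bias_amplitude`.

Defaults: 32^3 voxels, 8 subjects per class per domain, class_effect 1.0
on a base blob amplitude of 1.0 with subject variability 0.25,
modality_correlation 0.7, shift_gain 1.3, shift_smooth 0.75 voxels,
bias_amplitude 0.15, additive voxel noise 0.1.  These were chosen once to
give a clearly learnable but noisy task with a trivially detectable domain
gap (a mean-intensity threshold separates the domains with accuracy > 0.9),
which makes the adaptation problem non-vacuous at desk scale.  The
generator does not attempt brain anatomy, scanner physics, or any real
preprocessing chain; passing tests therefore demonstrate the mechanics and
contracts of the method, not clinical performance.

## Problem sizes used in the shipped experiments

Desk-scale experiments use a two-layer encoder (channels 4, 8; pooling
after both layers) so the whole adversarial loop runs in seconds per
epoch.  The ablation-direction experiment (full model vs MRI-only) runs on
32^3 volumes (6 subjects per class per domain, 12 + 6 epochs at learning
rate 5e-4) across 5 seeds and compares mean target-domain accuracy.  Its
task uses `class_effect = 0.6` split asymmetrically between modalities
(`modality_balance = 0.75`: MRI effect 0.3, PET effect 0.9) — PET more
class-sensitive than structural MRI, the clinical premise that makes the
single-modality variant information-limited — and the full model uses the
lossless sequence flatten.  Three sizing rules fix these choices:

* the source-domain fit must converge (training accuracy ~1) before the
  comparison is read out, otherwise it measures optimisation noise;
* each per-modality class effect stays below the base blob amplitude, as a
  larger effect inverts blob polarity under the intensity shift, producing
  anti-correlated transfer that label-free adaptation cannot repair;
* the fused width must not collapse at toy scale: the sequence mean is
  lossless at full size (L = 2, 256 -> 256) but would reduce a toy-scale
  sequence of L = 216 positions to 16 dimensions, making target-domain
  threshold calibration — not modality information — the binding
  constraint.

The head-count sweep runs {1, 4, 8, 16} heads on 16^3 volumes.  The full-size architecture is exercised by a single forward
pass on a 113 x 137 x 113 pair, verifying the 256-dimensional fused
feature analytically and numerically.

## Numerical implementation

The networks are built on an internal reverse-mode autodiff tape over
numpy arrays (`mmdda._autograd`, `mmdda.nn`).  3-D convolution forward and
both backward passes are expressed with `scipy.signal`
correlation/convolution, which switches to FFT for large volumes; max
pooling routes gradients to per-window argmaxes (ties split evenly in
composite reductions).  All computation is float64; gradient correctness
is verified against central differences throughout the test suite.

## Known limitations

* Single-threaded CPU training only; the reference-scale schedule (200
  epochs on full-size volumes) is configurable but impractical here.
* The correlation loss degenerates for distant features (see above); on
  synthetic data most of the adaptation work is done by the discriminator
  and consistency terms.
* Binary tasks only; no multi-class heads, no lambda annealing, no MMD or
  CORAL alignment alternatives.
* Decision-threshold calibration under domain shift dominates accuracy
  variance in small target samples; AUC is the more stable synthetic-scale
  readout.
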