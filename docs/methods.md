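# Methods

This note records what the package computes, the model and parameter
choices, and the known limits of the synthetic data. Every quantitative
statement here is something the code computes; nothing is claimed beyond
that.

## Problem setting

Given a greyscale image slice and a set of K binary organ-at-risk (OAR)
masks produced by *any* segmentation source, the package estimates a
voxel-wise probability that the segmentation is wrong at that voxel — a
confidence map — without access to a gold standard at inference time. The
training signal that makes this possible is the **distance-to-gold-standard
mask (d2GS)**: during training, where gold contours exist, a voxel is
labelled erroneous when any organ channel of the candidate segmentation
disagrees with the gold channel (`masks.compute_d2gs`, a channel-wise
exact-disagreement union).

## Models

Both networks operate on 2-D slices in channel-last layout and are
implemented in a small NumPy engine (`nn.py`) with exact analytic
gradients (verified against float64 finite differences in the test suite).

**Generator** (`networks.UNetGenerator`) — an 8-convolution U-net:
two encoder convs, 2×2 max-pool, two bottleneck convs (with dropout
p = 0.25 on the first), nearest-neighbour 2× upsample, skip concatenation,
three decoder convs, then a 1×1 projection to K+1 channels and a voxel-wise
softmax over background + K organs. Every 3×3 conv is followed by batch
normalization and ReLU. Input: the image slice (1 channel).

**Discriminator** (`networks.UResNetDiscriminator`) — a shallow U-ResNet:
a stem conv, two residual blocks, 2×2 max-pool, two residual blocks,
2× upsample, skip concatenation, a fusing conv, and a 1×1 head with a
voxel-wise 2-class softmax (correct vs erroneous). Input: K organ-mask
channels with the image as the **last** channel. The `ablate` option
zeroes either the image channel or the mask channels at the input, in both
forward and backward passes, for the input-ablation controls.

## Losses and adversarial training (`losses.py`, `training.py`)

The focal log loss of the probability assigned to the true class is

    FL(p) = −(1−p)^γ · log(p + ε),   γ = 2,  ε = 1e−7,

averaged over voxels. The generator objective combines its supervised
segmentation loss FL_G with an adversarial term driving the discriminator's
loss FL_D up:

    L_gen = α·FL_G + β·(1 − FL_D),   α = 20, β = 1.

Each batch performs one discriminator update (on the d2GS labels of the
current, binarized generator output against the gold masks) and one
generator update. The generator's binarization (argmax over the softmax) is
non-differentiable; the adversarial gradient is passed through it with a
straight-through estimator: the gradient reaching the discriminator's mask
input channels is applied directly to the corresponding softmax organ
channels. Optimization is Adam (default lr 2e−4 generator, 1e−4
discriminator).

During training, a configurable fraction of batches has **synthetic
errors** injected into the masks shown to the discriminator so it sees
error modes larger than the converging generator's own mistakes.

Two controls are implemented: a **sequential baseline**
(`train_sequential_baseline`: generator trained alone, frozen, then the
discriminator trained only on its outputs — no adversarial pressure, no
synthetic errors) and the two **input ablations** above.

## Synthetic error model (`errors.py`)

Independent per-case draws of:

- **rigid** rotation (nearest-neighbour inverse-mapping resample about the
  grid centre) and translation;
- **non-rigid** thin-plate-style deformation: a smooth displacement field
  sampled on a 20-voxel control grid with per-component magnitude σ and
  interpolated with `scipy.interpolate.RBFInterpolator` (thin-plate-spline
  kernel); larger σ displaces a monotonically larger fraction of mask
  voxels (tested over 200 seeds);
- **class perturbation**: relabelling voxels of one organ to the
  second-ranked softmax class (requires a softmax, so it is skipped when
  corrupting external masks);
- **OAR removal**: deleting one organ channel, all others bit-identical.

A global `magnitude_scale` scales the geometric magnitudes; scale 0 and
zero probabilities are exact identities.

## Post-processing

**Intelligent edge removal (IER, `postprocess.intelligent_edge_removal`)** —
predicted-error voxels within a k×k dilation (k = 3) of the Sobel edge
union of the segmentation are removed, then regrown where they lie within
Euclidean radius k/2 of a surviving error voxel (restricted to the band and
to originally-flagged voxels). The output is always a subset of the input.
This suppresses the trivial one-voxel boundary disagreements that dominate
raw error maps.

**Geometric distance correction (GDC,
`postprocess.geometric_distance_correction`)** — an *evaluation-stage*
reclassification of the confusion map only. For each FP/FN voxel, within a
clipped 31×31 patch: let D(x_tp) be the distance to the nearest
true-positive voxel and D(tp_max) twice the largest inscribed-disc radius
of the in-patch TP region (Euclidean distance transform with zero padding).
If D(x_tp) < D(tp_max) the voxel is reclassified (FP→TP, FN→TN). Decisions
use the original labels only (no cascading), TP/TN voxels never change, and
the confidence map itself is byte-identical before and after (asserted in
the acceptance suite). GDC therefore only removes FP/FN counts near
detected regions; it cannot create errors, and FPR/FNR are non-increasing
under it.

## Evaluation (`evaluation.py`)

Voxel-wise confusion of the thresholded confidence map (default 0.5)
against d2GS, reported overall and per OAR (per-OAR region = the
EDT-dilated union of predicted and gold organ, margin 10 voxels). Metrics:
MCC, FPR, FNR and the FP:FN ratio, each carrying a `nan` *undefined marker*
when its denominator vanishes (e.g. a case with no reference errors has
undefined FNR); undefined values are excluded from means, with the defined
count reported alongside. Four configurations are compared: baseline
(raw map), IER, GDC, and IER+GDC. Four-colour maps (TP green, FP pink,
FN blue, GDC-corrected yellow) are rendered for qualitative review.

## Synthetic phantoms (`phantom.py`) and their limits

Each slice contains K wobbled, non-overlapping ellipses ("organs") at
distinct intensity contrasts on a noisy, multiplicatively-shaded
background, optionally including a *tiny* organ (< 10 voxels) and a
*low-contrast* organ (contrast ≤ 0.8× the noise σ) to mimic hard clinical
structures. Per-slice seeds are spawned from one `SeedSequence` so datasets
are reproducible and slices mutually independent.

Realism limits to keep in mind: phantoms are 2-D, single-modality, with
piecewise-constant organs whose identity is carried *only* by intensity
contrast — there is no anatomical shape prior, no inter-organ spatial
context, no partial-volume effect, and the noise is i.i.d. Gaussian rather
than scanner-correlated. Conclusions drawn on phantoms demonstrate that the
mechanism works, not clinical performance.

## Numerical choices

- float32 forward/backward throughout training; float64 only in gradient
  verification tests.
- ε = 1e−7 sits inside the log (so FL(0) = 7·ln 10 exactly); γ = 2.
- MCC computed in float64 from integer counts; denominators of zero yield
  the nan undefined marker rather than a silent 0.
- All stochastic components take explicit integer seeds (< 2³¹); dataset
  seeds are spawned via `numpy.random.SeedSequence`.
- Checkpoints are `.npz` with a JSON metadata entry recording architecture
  hyperparameters and the ablation flag; loading reconstructs the exact
  model.

## Limitations

- The NumPy engine is CPU-only and single-threaded beyond BLAS; the
  reference scale (~200 64×64 slices, 12 epochs) trains in minutes, but
  clinical-resolution 3-D volumes would require a GPU framework.
- The discriminator's error maps at this scale leave many cases with
  undefined MCC before post-processing is applied; summary means exclude
  them and report `n_defined`.
- The straight-through estimator is a biased gradient; it is the standard
  pragmatic choice for the argmax binarization, not an exact one.
- GDC is only defined on confusion maps, i.e. it requires a gold standard,
  which is why it is strictly an evaluation-stage tool.
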