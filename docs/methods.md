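# Methods

## The model family

All networks are binary-segmentation codecs over single-channel 2D images:
an encoder halves resolution `depth` times (2×2 max-pool) while doubling
channels from `base_channels`, a decoder restores resolution with bilinear
2× upsampling followed by a 3×3 convolution, and a 1×1 convolution +
sigmoid head emits a per-pixel foreground probability. Inputs must be
divisible by `2^depth`; the CLI's `predict` reflect-pads other sizes and
crops back.

Three interchangeable blocks fill the codec:

* **standard** — (3×3 conv → BN → ReLU) × 2.
* **DAB** — 3×3 conv halving channels, then two parallel depth-wise
  branches each computing 1×3 then 3×1 (branch B dilated, default 2),
  branch sum, 1×1 conv restoring the output width, residual addition of
  the block input, final ReLU. When input and output widths differ the
  residual passes through a 1×1 projection; when a DAB position would
  receive an odd channel count (the raw 1-channel image) a standard 3×3
  conv stem is inserted first, since the block must halve its input. DAB
  trades parameters for efficiency: at matched widths it is several times
  smaller than the standard block, which is what produces the
  DAB-variants-are-smaller ordering checked in the tests.
* **MC** — 2×2 valid conv (spatial −1), 2×2 stride-1 transposed conv
  (spatial +1, implemented as a 2×2 conv on a 1-padded input with the
  kernel stored in conv layout — the two are algebraically identical),
  then a same-padded 3×3 conv; each layer has its own BN + ReLU. The
  first layer maps in→out channels; the rest keep out.

Topologies:

* **U** — the classic codec; all blocks are the configured kind.
* **N** — a precoding unit (block → pool → block → upsample → concat →
  1×1 merge, emitting `base_channels` maps at input resolution) whose
  output *replaces* the raw image as the U codec's input. Precoder and
  codec use the configured block.
* **W1** — a second encoder beside the primary one. The primary encoder
  (and its bottleneck) uses standard blocks; the secondary encoder and
  the decoder use the configured block. The secondary has exactly
  `depth` block+pool stages and no bottleneck; its deepest map is
  concatenated with the primary bottleneck output and 1×1-reduced before
  the single decoder. Decoder skips come from the primary encoder.
* **W2** — one standard-block encoder and two configured-block decoders.
  Decoder 2 starts from decoder 1's first upsampled feature map and runs
  skip-free to full resolution; the two full-resolution outputs are
  concatenated before the head. Skip-free was chosen because the second
  decoder is described only by its input; giving it the encoder skips as
  well would make it a duplicate of decoder 1 rather than a refinement
  path, and the skip-free form keeps its parameters attributable to
  resolution recovery. Both choices leave every parameter reachable by
  the loss (asserted per-parameter in the tests).

**Dense fusion.** Each block records its size-preserving internal
convolution outputs ("taps"; the MC block's shrunken first layer is
excluded since it cannot be concatenated at the level's resolution). With
`dense=True`, every decoder level concatenates the upsampled features,
the skip (where the decoder has skips), and all encoder taps of that
level, then 1×1-reduces back to the level's nominal width before the
block. In W1 both encoders contribute taps; in N the main encoder does
(the precoder operates partly at other resolutions and is treated as
input preprocessing); in W2 both decoders receive the taps. Dense
variants therefore strictly add parameters at fixed size — the second
structural ordering the tests assert.

Weights are Kaiming-uniform (ReLU gain) with zero biases from a
per-model seeded generator; two builds from one seed are bit-identical.
Convolutions followed by batch norm carry no bias: the norm's mean
subtraction would give such a bias an identically zero gradient, which
would also break the everything-gets-gradient invariant.

## Training protocol

Adam with learning rate 2e-3 and betas (0.5, 0.999); mean binary
cross-entropy loss with predictions clamped to [1e-7, 1−1e-7] (the
sigmoid head clamps to the same bounds, since float32 saturates to exact
0/1 beyond |logit| ≈ 17, and the output contract is the open interval);
up to 300 epochs by default, batch size 4 (unstated in the protocol this
follows; configurable). No schedule, weight decay, or early stopping.
When a validation set is supplied, the checkpoint with the best
validation Dice is restored at the end. Data order is drawn from the run
seed, so two CPU runs with one seed produce identical loss curves.

Dataset handling: 8:1:1 train/val/test split with remainder indices
assigned to train (200 → 160/20/20); 5-fold cross-validation with fold
sizes differing by at most one; both deterministic per seed.

## The phantom generator

The generator emulates what the networks consume in the intended
application — sagittal lumbar MRI slices with vertebra masks — at desk
scale: `n_bodies` (default 5) bright rounded quadrilaterals
(superellipses of exponent 3, so the profiles keep corners and exercise
boundary metrics) stacked along a quadratic, lordosis-like bowed
centerline, separated by darker disc gaps, on a noisy darker background.
Defaults: 64×64 canvas, foreground mean 0.8, background 0.2, Gaussian
noise σ = 0.05, gap 25% of a body slot, curvature 3 px; an optional
smooth multiplicative bias field (off by default) emulates MRI
inhomogeneity. Construction guarantees: bodies are pairwise disjoint
(full background rows separate them, so the mask has exactly `n_bodies`
connected components under 4- or 8-connectivity), and thresholding the
noise-free image at the fg/bg midpoint reproduces the mask exactly — a
perfect score on all seven metrics is achievable by construction.

What the phantoms do *not* model: real MRI texture, partial-volume and
bias-field artefacts at realistic strength, anatomical variability,
neighbouring bone structures with similar intensity, or 3D context.
Passing the phantom experiments therefore demonstrates that the
architectures, losses, metrics and pipeline are implemented correctly
and can learn a spine-shaped segmentation task — not that any variant
reaches a particular accuracy on clinical data.

## Scaled-down experiment sizes

The package's standing experiment trains DenseMCW1-Net at depth 3 /
width 8 on 16 phantoms (64×64, noise σ = 0.03, seed 0) for 150 epochs —
sizes chosen so the full suite runs comfortably on a single CPU while
still exercising every architectural mechanism (dual encoders, dense
merges, best-checkpoint selection). Under these conditions the final
training loss falls below 1% of the epoch-1 loss and training-set mean
Dice reaches 1.0. Full-scale results on clinical datasets (512×512,
depth 4, width 64, 300 epochs) are out of scope here and would require
GPU-scale resources.

## Numerical choices and conventions

* Binarisation threshold 0.5, ties (p = θ) to foreground.
* Degenerate metric ratios: 0/0 → 1 when the relevant sets are empty on
  both sides, else 0 (an empty prediction of an empty truth is perfect).
* BF-Score: 4-connectivity inner boundary (8 available), image border
  counts as background, Euclidean distances via an exact distance
  transform (verified identical to all-pairs matching), θ inclusive.
* Per-dataset scores are unweighted means of per-image scores (macro).
* Max-pool ties route to the first maximum — deterministic backward.
* Bilinear upsampling uses half-pixel-centre (align-corners-false)
  interpolation expressed as fixed row/column matrices; its adjoint is
  the exact backward.
* Augmentation: rotation uniform ±15°, translation uniform ±10% per
  axis, flip = up–down, mirror = left–right; masks warp with
  nearest-neighbour, out-of-canvas regions are background. Magnitudes
  are package defaults chosen to keep anatomy plausible; each emitted
  pair records its transform so co-registration can be re-verified.
* Image loading min-max scales to [0, 1]; constant images map to all
  zeros. Mask encodings 0/255 map to {0, 1}.
* Batch-norm: momentum 0.1, eps 1e-5, unbiased running variance;
  evaluation always uses running statistics.

## Known limitations

* The engine is CPU/numpy: fine at test scale, far too slow for
  512×512 × width-64 training.
* Only stride-1 convolutions are provided; downsampling is pooling-only,
  which matches these architectures but not arbitrary ones.
* The published parameter counts of the original full-scale networks
  cannot be matched absolutely (channel schedules unpublished); only
  the orderings between variants are asserted.
* BF-Score uses thresholded coverage matching, not one-to-one
  assignment; the two differ only when several boundary pixels compete
  for one match within θ.
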