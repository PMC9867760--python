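# Methods

## Model

PSNet is a dual encoder–decoder for binary polyp segmentation of colonoscopy
frames. Two encoders read the same H×W RGB frame in parallel:

* **PS encoder** (CNN branch): four identical stages of 2×2 max-pooling
  followed by a local-feature-extraction (LFE) module, producing a pyramid
  at 1/2, 1/4, 1/8 and 1/16 resolution with channels 64, 128, 256, 512.
  An LFE is two depthwise-separable convolutions (3×3 depthwise + 1×1
  pointwise, batch norm, SiLU; the first carries the channel change)
  followed by a CCM: depthwise 1×3, 3×1, 3×3 at dilation 2 (PReLU closes
  the group), then 1×5, 5×1, 5×5 at dilation 3 (ReLU6 closes the group),
  batch norm after every convolution. The k=5, d=3 layer covers
  d·(k−1)+1 = 13 pixels per axis.
* **Transformer encoder**: a plain ViT — P×P patches linearly embedded with
  learned positional embeddings, L pre-norm blocks of multi-headed
  self-attention (scale 1/√(d/heads)) plus a GELU MLP, final layer norm.
  No class token; the decoder needs exactly N = (H/P)² patch tokens.

Decoding produces six full-resolution, single-channel **candidate maps**:

* the **partial decoder** projects each token to μ tissue logits (μ = 64 by
  default; each channel can specialize on a pixel condition such as boundary
  or specular highlight) and rearranges them into a (μ, H/16, W/16) grid;
  the **enhanced dilated transformer decoder** lifts that grid to full
  resolution (×4 upsample → double 3×3 convolution → ×4 upsample → double
  dilated convolution at rate 3 → pointwise 64→32→1);
* the **PS decoder** mirrors the encoder with four ×2-bilinear-upsample +
  LFE stages, concatenating encoder skips at 1/8, 1/4 and 1/2, with wSq
  attention after stages two and three and SCSE after stage four, and a
  final pointwise convolution;
* four **merge modules**, one per pyramid scale, each concatenating the CNN
  feature map with the (resized) μ-logit grid, projecting to a constant 64
  channels, running two maxpool + double-separable-conv steps down and two
  upsample + double-separable-conv steps back up, then upsampling to full
  resolution and reducing to one channel.

The six pre-activation maps are averaged elementwise and one sigmoid gives
the polyp probability map. Training minimizes 1 − softIoU(σ(x̄), y) with
ε = 1e-6 in numerator and denominator; the deep-supervision signal reaches
every branch through the shared mean. The printed form of the training
objective is the IoU ratio itself; a network minimizing that ratio would
minimize overlap, so the implemented loss is its complement — this is a
deliberate reading, flagged here.

With an all-zero mask the ε convention drives the loss to zero only once
Σσ(x̄) ≪ ε, i.e. for strongly negative logits (≈ −40 at 8×8); at logits −20
the residual loss is ≈ 0.12. Metrics are per-image Dice and IoU of the
0.5-thresholded prediction, averaged per source dataset and then unweighted
across datasets (empty-vs-empty scores (1, 1)).

## Attention gates

Both decoder gates implement y = x·gate_a(x) + x·gate_b(x).

* **wSq**: gate_a = σ(PW(PW(WAP(x)))) where WAP is average pooling
  (default kernel 7, stride 1, padding 3) whose denominator always counts
  the padded zeros — border windows are down-weighted, which is the
  "weighting". gate_b = σ(PW₁(x)) with one output channel broadcast across
  channels. The WAP geometry was reported only as "chosen through
  parametric studies", so it is fully configuration-exposed. The published
  description swaps the cSE/sSE labels relative to the usual convention;
  this implementation is named by structure.
* **SCSE**: the standard concurrent pair — channel gate from global average
  pooling through a reduction-2 bottleneck, spatial gate from a one-channel
  pointwise convolution, combined additively.

## Parameters and defaults

| parameter | default | note |
|---|---|---|
| image size | 512 (tests: 64) | must divide by 16 and by P |
| encoder channels | 64,128,256,512 | only the final 512 is published; doubling schedule inferred from the pyramid convention |
| decoder channels | 256,128,64,32 | mirrors the encoder |
| μ (tissue logits) | 64 | published sweep: 1/32/64/128, best at 64 |
| ViT variant | B/16 (d=768, L=12, 12 heads) | the published lineage's standard; a 2-layer d=64 "tiny" variant is first-class for tests |
| WAP kernel/stride/pad | 7/1/3 | unpublished; exposed |
| loss ε | 1e-6 | |
| threshold | 0.5 | unpublished; standard |
| epochs / batch | 400 / 16 | published |
| initial lr | 2.1052e-5 | published |
| peak lr | 2.1052e-4 | the ramp target is unpublished; default is 10× the initial rate, exposed |
| warm-up / decay power | 20 epochs / 0.98 | published |
| init | N(0, 0.02²) conv+linear; norm scale/shift exactly 1/0 | published |

Upsampling everywhere is bilinear (half-pixel convention); the two
transformer-decoder upsamplings are ×4 each, the only symmetric split that
reaches full resolution from 1/16. Positional embeddings are bicubically
interpolated when loading checkpoints trained at another resolution.

## Ablation variants

`no_transformer` removes the ViT, partial and enhanced decoders and routes
only CNN features into the merges (5 streams). `no_dual_decoder` replaces
all decoding with concat → pointwise → bilinear upsample of the deepest
features (1 stream). `no_merge` keeps the two branch decoders (2 streams).
`no_ps_encoder` removes the CNN branch and its decoder; merges consume only
the logit grid (5 streams) — the published account names only what is
removed, so this mirrors the transformer ablation symmetrically. `no_ccm`
replaces every LFE's CCM with identity. The averaged map always
renormalizes over the streams present.

## Compute backend

The network runs on a compact NumPy reverse-mode autodiff engine
(`psnet.nn`) written for exactly this op set: dense/pointwise/depthwise
convolution (asymmetric and dilated), max/average pooling, separable
bilinear resizing, batch/layer normalization, multi-headed attention
primitives, and Adam. Dense convolutions use an im2col buffer and one
channel matmul; depthwise convolutions use Numba-compiled scalar loops;
bilinear resizing is a pair of row-stochastic interpolation matrices whose
backward is their exact transpose. Every op's gradient is verified against
central finite differences in float64, and the convolution forward against
scipy.signal. Forward passes are float32; one full-scale (512², ViT-B/16,
88M parameters) inference takes ≈30 s and ≈2.3 GB on one CPU core.

Batch-norm degeneracy: in training mode with a single sample and 1×1
spatial extent (the deepest merge scale at 64² input), per-channel batch
statistics make the output constant and annihilate that path's gradient.
Gradient-flow checks therefore use batch ≥ 2; real training batches are
never degenerate.

## Synthetic data

The generator emulates what the architecture is sensitive to, not
photorealism: mucosa-toned backgrounds with two scales of smoothed-noise
texture, a circular dark vignette, and 0–3 polyps as rotated anisotropic
ellipses radially perturbed by a low-order Fourier series (smooth,
blob-like boundaries), brightened/reddened by at least the configured
contrast, with their own texture and a soft specular highlight; the mask is
the exact rasterized support. It does not emulate instrument artifacts,
motion blur, fluid, or the texture statistics of real mucosa — passing
tests demonstrate that the pipeline learns and evaluates correctly, not
clinical performance. One seeded generator drives everything, so equal
configurations give byte-identical PNGs.

## Split protocols

Standard protocol: per source, ⌈10%⌉ is held out as test (100/1000 and
62/612), the remainders pool to 1450 training images, and validation is a
⌈10%⌉ subsample of that pool. The published per-dataset summary counts the
validation images inside the training column, which is why its rows
over-count (900+90+100 = 1090 for a 1000-image set); here the split tags
always partition. Merged protocol: all five sets pool to 2248, shuffled;
224 test, 224 validation, 1800 train. The published merged-table train
count (2023) exceeds the partition arithmetic by one; the discrepancy is
noted rather than matched. The published cross-dataset mIoU mean is quoted
as 0.797 while the per-dataset row averages to 0.7976 (rounds to 0.798);
reporting code returns the computed value.

## Problem sizes in tests and the acceptance script

Shape contracts run once at full scale (512², ViT-B/16) and elsewhere on
the tiny configuration (64², 2-layer d=64 ViT, full channel schedule). The
overfit-recovery probe trains the tiny network on 8 synthetic 64² frames
(Adam, constant 2e-3, batch 4, ≤200 steps, early stop at training
mDice ≥ 0.95); it typically reaches the target within ~100–160 steps.
These sizes were chosen so the whole suite exercises every code path on a
single CPU core.

## Known limitations

* No multi-GPU, mixed precision, or data augmentation; preprocessing is
  resize + (v−0.5)/0.5 normalization only, as published.
* Absolute benchmark scores on the public datasets require the real data
  and long training; nothing here claims them.
* Pretrained ViT weights are supported through the checkpoint loader
  (name-mapped tensors, positional-grid interpolation) but not shipped.
* The reference execution mode is single-threaded CPU; determinism
  guarantees apply there.
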