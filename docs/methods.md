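# Methods

This note documents the models and procedures implemented in `stemseg`, the
choices made where the design was genuinely open, and what the synthetic
study conditions do and do not establish about real data.

## Segmentation network

RAM-UNet is an encoder–decoder segmenter with two output classes
(background, main stem).

**Encoder.** A ResNet50-style backbone: 7×7 stride-2 stem, 3×3 stride-2 max
pool, then four bottleneck stages (3, 4, 6, 3 blocks) at output strides 4,
8, 16, 32. The 3×3 convolution of every bottleneck can be replaced by a
deformable convolution (configurable per stage; all four stages by
default). The deformable operator is the offset-only variant: a parallel
convolution of identical geometry predicts a (Δrow, Δcol) pair per kernel
tap and output position; taps are gathered by bilinear interpolation, and
samples outside the canvas contribute zero. The offset branch is
zero-initialized, so a freshly built deformable network computes exactly
what its standard counterpart does — this keeps pretrained standard weights
valid and is verified by an equivalence test at build time. No modulation
scalar is used.

**Context block (C-ASPP).** On the stride-32 feature: a 1×1 branch, one 3×3
atrous branch per dilation rate, and a global-average-pooling branch whose
1×1-projected output is broadcast back over the grid; branch outputs are
concatenated and fused by a 1×1 projection. Default rates are (1, 2, 7, 15).
A rate set is accepted only if gcd(r₁,…,rₙ) = 1; sets with a common factor
(e.g. 6, 12, 18 or 2, 4, 8) sample a sparse lattice whose blind spots cut
thin continuous structures (gridding). Strict validation can be disabled to
build such sets for ablation. CBAM follows each atrous branch; whether it
also follows the pooling branch is exposed as a flag (default off — the
pooling branch carries a single global context vector for which spatial
attention is degenerate).

**CBAM.** Channel attention: shared two-layer MLP (reduction 16, floor 1)
applied to global average- and max-pooled vectors, summed, sigmoid. Spatial
attention: 7×7 convolution over the channel-wise [avg; max] stack, sigmoid.
Both maps multiply the feature sequentially (channel first).

**MSAA.** Skip features are refined before decoder fusion: 1×1 reduction
C → D, parallel 3/5/7 convolutions summed into U, a spatial weight map
Ws (1×H×W) and a channel weight vector Wc (D×1×1) both derived from U,
modulating the reduced feature Z (Us = Ws⊙Z, Uc = Wc⊙Z), and a residual
output K = conv₁ₓ₁(Us ⊙ Uc) + N. The internal derivation of Ws and Wc is
not fixed by the block's defining equations, which give only their shapes
and (0,1) range; this implementation derives them with the CBAM idiom
already present in the architecture (Ws from a 7×7 convolution over
channel-pooled U; Wc from the pooled-MLP construction), isolated behind
`spatial_gate` / `channel_gate` so alternatives are swappable. D defaults
to max(C/4, 8) clamped to C.

**Decoder.** From the context feature: three fusion levels, each a ×2
bilinear upsample, MSAA on the corresponding skip (strides 16, 8, 4),
channel concatenation, and a 3×3 convolution + BN + ReLU smoothing. A 1×1
classifier and a final ×4 bilinear upsample restore input resolution.
Prediction is the per-pixel argmax; exact ties resolve to background.
Inputs must be divisible by 32.

**Width scaling.** Every nominal channel count is multiplied by
`width_mult` (floor 4). Tests use 1/8; the full model is 1.0.

## Objective and metrics

With per-pixel foreground probability pᵢ (sigmoid of the two-class score
margin) and binary labels gᵢ:

- L_CE = −(1/N) Σ [gᵢ ln pᵢ + (1−gᵢ) ln(1−pᵢ)], probabilities clamped to
  [1e-7, 1−1e-7];
- L_Dice = 1 − (2Σpᵢgᵢ + ε)/(Σpᵢ + Σgᵢ + ε), ε = 1e-6 rescuing the empty
  0/0 case;
- L_CD = α·L_Dice + (1−α)·L_CE.

α is exposed in `LossConfig` and defaults to 0.5 — the source recipe for
this composite does not state the weight it used, so equal weighting is the
documented neutral choice. Metrics come from one global confusion matrix
accumulated over all pixels of a dataset: per-class IoU = TP/(TP+FP+FN),
mIoU the mean over background and stem (classes with an empty union are
excluded), Recall/Precision/F1 for the stem class, all in percent. The
printed single-class IoU formula that sometimes accompanies the name
"mIoU" in this literature is ambiguous; averaging both classes of the
binary task is the convention adopted here and stated wherever numbers are
reported.

## Training

Adam (β = 0.9/0.999, no weight decay — only the learning rate is prescribed
by the recipe), cosine annealing per epoch
lr(e) = lr_min + ½(lr0 − lr_min)(1 + cos(πe/total)), batch 4, 300 epochs,
input 512×512. The first 100 epochs freeze the encoder so the decoder,
context block and attention modules adapt to the task before pretrained
backbone weights are touched; from epoch 100 everything trains. Validation
runs every 10 epochs and at the final epoch; the best checkpoint is the
highest validation mIoU, ties to the earlier epoch. "Best" and "last"
checkpoints are single `.npz` archives holding weights, buffers, config and
epoch. All randomness (initialization, shuffling) derives from the config
seed; identical configs reproduce identical loss trajectories on the same
hardware.

The numerical core is a small reverse-mode autodiff engine on numpy arrays
(im2col/GEMM convolutions, bincount-scatter adjoints for the deformable
gather, separable linear-map bilinear resizing). Every operator is verified
against central finite differences in float64, and the deformable/CBAM/MSAA
operators additionally against naive loop re-implementations.

### Scaled-down study conditions

Full-scale training is GPU-sized; the test suite instead trains a ⅛-width
network on 96×96 renders: 48 training images (12 plants × 4 views), 24
held-out images (6 plants), 20 epochs, batch 4. For this from-scratch run
the freeze phase is disabled (there are no pretrained weights to protect)
and the learning rate is 7e-3 annealed to 3.5e-4, chosen by a pilot run of
the scaled-down configuration — at 240 optimizer steps the full-scale 1e-4
rate leaves the network far from convergence. The run reaches a held-out
stem IoU of ~0.75, against a required floor of 0.70.

## Synthetic data generator

Each plant is a cubic Bézier main stem swept with a linearly tapering width
(discs stamped every 0.25 px of arc, guaranteeing a connected band whose
medial axis tracks the curve), rendered on a near-black background with
mild sensor noise. Morphology classes carry 0 (simple), 1 (double) or 2–4
(complex) side branches — thinner Béziers attached to the stem, drawn in
the image but excluded from the mask, which covers the main stem only.
Pod-like ellipses with hue within ±10° of the stem hue are drawn *over* the
stem near its band; placements that would fully sever the visible band are
re-sampled (up to 20 rounds, then with fewer pods), so exactly one visible
stem component survives. An axis-aligned ruler of known physical length is
rendered in a reserved top margin with per-centimetre ticks; its endpoints
(recorded in a metadata sidecar, never in the mask) make the cm/px factor
exactly recoverable. Four views per plant apply exact 90° rotations of the
geometry before rasterization; plant geometry is confined to the inscribed
disc so every view stays on canvas, and lengths are rotation-invariant by
construction. `true_length_cm` is the numeric arc length of the stem Bézier
(4096-point polyline, converging to the 10⁵-sample reference well below
0.1 %) divided by px/cm.

Parameter choices: stem width is ~1.8–3 % of the frame, matching mature
plants photographed at 3024×4032 and downscaled to 512 (stems ~7–10 px),
with a 4 px floor so that reduced test canvases (96–256 px) keep the same
object-to-stride regime rather than dropping below the resolvable width;
stem hue 0.08–0.13 (tan/brown), pods 5–12 per plant; default calibration
20 px/cm at 512, scaled with canvas.

**What passing on this generator shows — and what it does not.** The
generator reproduces the *structural* difficulties of the task: thin curved
targets, same-hue occluders that must be excluded from the mask, branch
distractors, class imbalance (~2 % foreground), and exact length ground
truth. It does not reproduce photographic texture, illumination variation,
leaf litter, specular ruler markings, or annotation noise; a network that
learns the synthetic task has demonstrated the architecture's capacity to
separate geometry and suppress same-color occluders, not field readiness.

## Length measurement

1. **Calibration.** r = RL_real / RL_pixel, where RL_pixel is the endpoint
   distance (if endpoints are given) or the maximum pairwise distance
   between ruler foreground pixels, computed on the convex hull with a
   brute-force fallback for degenerate (collinear) masks.
2. **Skeleton.** Morphological closing with a disc (radius 2 px at 512,
   scaled with image size, floor 1) bridges small prediction gaps; the
   largest 8-connected component is thinned to a one-pixel skeleton; an
   8-connectivity graph with Euclidean edge weights (1, √2) is built; the
   returned centerline is the maximum-weight geodesic between skeleton
   endpoints (degree-1 nodes, enumerated exhaustively — pods and branches
   create short spurs that this step discards). Cyclic skeletons without
   two endpoints fall back to a double-sweep farthest-point search.
3. **Length.** L_pixel = Σ √(Δrow² + Δcol²) over consecutive path pixels;
   L_real = L_pixel · r.

The stem length is defined as the path length *along* the centerline, not
the base-to-apex chord: the two definitions coincide only for straight
stems, and the curved-stem ground truth used throughout is the arc length.

**Error budget.** The digital 8-connected path overestimates a smooth
curve's length by up to ~8 % depending on orientation (steps are quantized
to 1 and √2), while thinning erodes roughly one half-width at each tip;
on the synthetic population the net bias is about +4–5 %, within the 5 %
median-recovery tolerance the tests enforce. The bias is scale-invariant,
so higher-resolution masks do not remove it; applications needing tighter
absolute accuracy should calibrate it out against known-length references.

## Dataset plumbing

- **Rasterization** uses pixel centers (col+0.5, row+0.5) and the nonzero
  winding rule, validated against an exhaustive point-in-polygon oracle;
  LabelMe JSON is read keeping polygon shapes only (others are logged and
  skipped).
- **Splitting** is by whole plants, stratified by morphology class, seeded;
  per-class training quotas come from largest-remainder rounding
  constrained to a global total of round(ratio·N) — for class sizes
  divisible by the ratio (150/120/80 at 0.8) the per-class counts are exact
  (120/96/64), and the rule stays well-defined otherwise. Rounding is
  half-up for platform stability.
- **Augmentation** (rotation ±15°, crops retaining ≥80 % area, horizontal
  flip, HSV perturbation ±10° hue / ±20 % sat/val, Gaussian noise σ ≤
  10/255) applies geometric transforms identically to image and mask (mask
  nearest-neighbor, kept binary) and photometric transforms to the image
  only; ranges are package defaults since the source recipe names the
  operations but not their magnitudes.
- **VOC layout** writes JPEGImages/, SegmentationClass/ and
  ImageSets/Segmentation/{train,val}.txt; reading it back reconstructs the
  manifest and split exactly (basenames encode plant, class and view).

## Known limitations

- Training is single-process CPU float32; full-scale 512×512 / 300-epoch
  runs are out of reach here (the architecture and loop are the same at
  every scale — only problem sizes differ).
- ImageNet-pretrained encoder weights are not bundled; transfer-learning
  behavior (the main purpose of the freeze phase) is exercised
  mechanically, not scientifically.
- The ±10° pod hue band and pod geometry are stand-ins; no quantitative
  color distribution of real pods was available to emulate.
- The skeleton-path length estimator carries the systematic digital-path
  bias described above.
- Exact parameter-count parity with any particular reference
  implementation is not a goal; reported counts in this literature vary
  with bookkeeping conventions.
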