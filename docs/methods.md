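# Methods

## Problem and model

`echoseg` segments four structures in 2D apical echocardiograms —
background, left ventricle (LV), myocardium and left atrium (LA), encoded
0–3 — from a small labeled subset plus a pool of unlabeled images. The
method has two branches over one shared network:

* **Supervised branch.** A U-Net encoder–decoder with a 1×1-convolution
  classifier head minimises mean pixel-wise cross-entropy
  `L_ce = -(1/N) Σ_i Σ_c y_ic log p_ic` on labeled images.
* **Unsupervised branch.** Each unlabeled image is randomly cropped twice
  (with a guaranteed overlap region) and each crop independently
  photometrically perturbed. The same network and the *same classifier
  object* predict on both views; a projector head maps decoder features
  pooled to a coarse grid into an embedding space. The branch minimises
  `L_cl = L_ce + λ·L_dc` with λ = 0.1, where the first term is
  confidence-gated cross-view pseudo-label cross-entropy and the second the
  pixel-wise directional contrastive (DC) loss.

The DC loss is InfoNCE-like over overlap-grid locations. With
`r(a,b) = exp(cos(a,b)/τ)`, anchors φ₁, positives φ₂ (same source pixel in
the other view), and negatives φ_n:

```
l_dc(φ1, φ2) = -(1/N) Σ_hw M_dpf(h,w) · log[ r(φ1,φ2) / (r(φ1,φ2) + Σ_n r(φ1,φn)) ]
```

`M_d = 1{max_C f_1 < max_C f_2}` selects pixels where the anchor view is
strictly *less* confident than the positive view, so alignment is always
pulled toward the more reliable prediction; `M_dpf = M_d · 1{max_C f_2 > γ}`
additionally drops pairs whose confident side is still weak. The batch loss
symmetrises both directions and averages over the batch. `N` counts
overlap-grid locations — the only places both embeddings exist (the
alternative, all grid locations, only rescales the term).

## Architecture

Classic U-Net topology: per stage two 3×3 convolutions, each followed by
batch normalisation and ReLU; 2×2 max-pooling between encoder stages with
channel doubling (base 64 up to 1024 at the bottleneck for the full-size
network); decoder stages upsample (nearest-neighbour ×2 + 3×3 convolution
halving channels), concatenate the skip connection and apply another conv
block; a 1×1 convolution maps decoder output to 4 class logits. The stated
downsampling stages replace their convolutions with dilated ones (default
schedule `[1, 1, 2, 4]`: stages 2–4 at rates 1, 2, 4). Padding equals the
dilation rate, so every feature map keeps the exact shape of the undilated
network and the parameter count is unchanged — asserted by tests.

The projector is two per-pixel linear layers (1×1 convolutions), the first
followed by batch normalisation and ReLU; output dimension 256 (tiny preset
32). It consumes decoder features average-pooled to stride 8 (a 40×40 grid
for 320×320 crops). Placing the contrastive loss on the decoder side and on
a coarse grid are interpretation choices: the source description does not
fix the feature map feeding the projector, and a coarse grid keeps the
pairwise term tractable while matching the crop-to-grid arithmetic.

Ablation switches reproduce three variants: `baseline` (all-ones dilation,
no projector — plain U-Net), `dilation` (dilated stages, contrastive loss on
raw pooled features), `dilation_projector` (the full method).

Because no deep-learning framework is part of the dependency set, the
network runs on the package's own reverse-mode autodiff engine
(`echoseg.nn`): numpy tensors with hand-written backward passes for
convolution (im2col + GEMM), pooling, upsampling, batch normalisation and
the elementwise/reduction ops the losses need. Every op is verified against
central finite differences in the test suite.

## Augmentation and overlap bookkeeping

Supervised-branch transforms (each behind an independent Bernoulli gate,
default probability 0.5): horizontal flip (applied to image and mask),
Gaussian blur (σ ∈ [0.1, 1.5] px), intensity jitter. "Color jitter" on
single-channel ultrasound is implemented as brightness/contrast/gamma
jitter; grayscale conversion is an identity for 1-channel input and kept
only as a flag. Outputs are re-clipped to [−1, 1].

For the dual views, the random rotation (±15°) is applied **once to the
source image before both crops are taken**. This is the largest
interpretation choice in the package: per-view rotations would destroy the
exact pixel correspondence on the overlap that the DC loss assumes, so the
rotation is shared and correspondence stays exact (tested pixel-for-pixel
with photometric transforms disabled). Crop origins are drawn by rejection
until the intersection reaches `min_overlap_fraction` (default 0.25) of the
crop area; after a bounded number of failures the second origin is
resampled inside the feasible offset box, so the call never fails.

Overlap rectangles are mapped to the loss grid conservatively: only grid
cells whose pixel footprint lies entirely inside the overlap are kept
(starts ceiled, ends floored), and the two rectangles are trimmed to a
common size so they stay congruent for any stride. Overlaps smaller than
one grid cell are reported empty and the pair contributes nothing.

## Training schedule

SGD with momentum 0.9 (unstated in the source; standard), weight decay
1e-4, initial learning rate 0.01, poly decay `lr0·(1−epoch/total)^0.9`
applied per epoch (the schedule's iteration counter is defined in epochs).
The first 5 of 80 epochs train the supervised branch alone; afterwards each
step consumes one labeled and one unlabeled batch and backpropagates
`L_ce(labeled) + L_ce_pseudo + λ·L_dc` in a single update. Labeled
supervision is kept after warm-up — dropping it would make the labeled
ratio irrelevant, contradicting the observed dependence of accuracy on it.

Negatives: for each anchor pixel, `negatives_per_anchor` (default 64)
embeddings are sampled with replacement from the loss-grid embeddings of
the *other* images in the unlabeled batch (both views), excluding
candidates whose pseudo-label equals the anchor's pseudo-label. This makes
"semantically dissimilar content from other training images" concrete and
batch-computable without a cross-step memory bank. τ = 0.1 and γ = 0.75
follow the published settings of the predecessor context-aware-consistency
method, since the source names both symbols but prints neither value; both
are configuration-exposed.

The pseudo-label cross-entropy is computed symmetrically (each view scored
against the other's argmax, averaged) on the loss grid, restricted to
pixels where the pseudo-labeling view's confidence exceeds γ; with no
confident pixel the term is zero. Logs are clamped at 1e-12 throughout.
Zero embedding vectors are defined to have cosine 0 (kernel 1).

Validation: 10% of training patients (taken from the labeled pool, since
checkpoint selection needs masks) are held out and the checkpoint with the
best mean IoU is kept; with `val_fraction = 0` the final model is kept.
Splits are made at the patient level so the images of one patient never
straddle the labeled/unlabeled/test boundary; the labeled count is
`round(n·ratio)` with ties-to-even, floored at one patient.

## Synthetic phantoms

The phantom generator emulates the three stated challenges of
echocardiography — low contrast, incomplete structures, unclear borders —
on a sector-shaped field of view: a dark elliptical LV cavity, a bright
myocardial shell of configurable thickness, and a dark LA ellipse adjacent
to the LV across the valve plane (label priority LV > myocardium > LA where
shapes overlap). Corruptions, in order: linear contrast reduction toward
the tissue mean; Gaussian boundary blur; multiplicative unit-mean
Rayleigh speckle (a standard ultrasound speckle approximation,
`img · (1 + s·(R−1))`); and, with probability 0.25 per image, apical
truncation that blanks the top of the sector. The mask always encodes the
uncorrupted geometry. Generation is bit-reproducible given the parameter
seed, and the clean-geometry case is tested against a per-pixel
ellipse-inequality rasterisation.

Dataset-level variability (`sample_phantom_params`): semi-axes and shell
thickness jittered ±18–25%, centres by a few percent of the image, contrast
uniform in [0.55, 0.95], speckle strength in [0.2, 0.45], blur σ in
[0.5, 1.5] px at 64×64. These were fixed once as a plausible emulation of
clinical variability. What phantoms do **not** model: anisotropic
point-spread functions, attenuation shadows, valve/papillary anatomy,
probe-dependent gain maps, inter-observer label noise. Passing the phantom
benchmark therefore demonstrates that the training machinery extracts
unlabeled signal under controlled conditions, not clinical-grade accuracy.

## Phantom benchmark (desk scale)

32 training phantoms (64×64) with one quarter labeled, 8 test phantoms, 40
epochs, tiny backbone preset (base 8, depth 3, projector dim 32), dual-view
crops of 40×40 (the same crop-to-image ratio as 320 on 512), batches of 4,
three seeds. Compared arms: the full method (`dilation_projector`,
two-branch schedule) versus the plain U-Net baseline trained
supervised-only on the same labeled quarter. Reported: mean foreground DSC
(classes LV/myocardium/LA) and four-class mean IoU averaged over seeds.
These sizes were chosen so the whole comparison trains in minutes on one
CPU while leaving the supervised baseline visibly short of data.

## Metrics

Per class, from one-vs-rest pixel counts: `DSC = 2TP/(2TP+FP+FN)`,
`IoU = TP/(TP+FP+FN)`, `precision = TP/(TP+FP)`, `recall = TP/(TP+FN)`.
Aggregates are unweighted means over the four classes including background;
the spread statistic D(·) is the population variance of per-case means
across evaluation cases. Empty-class convention: 1.0 when the class is
absent from both prediction and truth, 0.0 when absent from exactly one.
Evaluation always runs at full preprocessed resolution, never on crops.

## Numerical choices and degenerate inputs

* Min–max normalisation to [−1, 1] per image; a constant image maps to 0.
* Images resize bilinearly, masks nearest-neighbour with anti-aliasing off,
  so resizing can never invent a label.
* Softmax uses a detached max-shift; cross-entropy and the DC ratio clamp
  logs at 1e-12; embedding normalisation adds 1e-24 inside the square root
  so gradients stay finite at exactly-zero vectors.
* Max-pooling breaks ties by first occurrence; the `max` reduction used in
  losses splits gradient evenly among ties.
* Empty overlap grids contribute zero loss with a logged warning; a joint
  step with every overlap empty still performs the supervised update.
* Training is deterministic given the configuration seed: one generator
  drives splitting, augmentation draws and negative sampling.

## Known limitations

* Still frames only (ED/ES); no echo video, no DICOM.
* The 2CH and 4CH models are trained separately by manifest filtering
  (joint training is possible but not the default, mirroring per-view
  reporting).
* Automatic mixed precision is accepted as a flag but is a no-op in the
  numpy engine.
* CPU-scale throughput: the full-size network (base 64, 512×512) forwards
  in seconds, so full-dataset training at scale is out of scope here;
  the tiny preset is the intended test vehicle.
* Whether the projector should read encoder or decoder features is an open
  interpretation; decoder-side is implemented.
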