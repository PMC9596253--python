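# Methods

## Problem and model

`ctcascade` segments small, bright, irregular lesions (the motivating case:
renal tumors in unenhanced abdominal CT) with a two-stage cascade:

1. **Localization (A1).** Every axial slice is scanned by a detector that
   returns confidence-scored axis-aligned boxes. Each box is expanded by a
   fixed 10-pixel margin on all four sides (clamped at the slice border)
   and cropped out. The expansion guarantees boundary context around the
   lesion; the crop is the "coarse segmentation".
2. **Fine segmentation (A2).** Each crop, replicated to three channels,
   passes through a shallow U-shaped encoder–decoder with an embedded
   feature pyramid, producing per-pixel two-class logits at full crop
   resolution. Predicted masks are pasted back at their crop offsets;
   overlapping crops are unioned (logical OR — deterministic and
   recall-preserving). Slices without detections stay background.

The rationale for the cascade is the extreme foreground imbalance: the
lesion occupies a small fraction of a minority of slices, so a whole-slice
segmenter spends almost all of its capacity and its loss on background.
Restricting A2 to margin-expanded detections removes most of that
imbalance and, symmetrically, lets A2 veto A1 false alarms.

### A2 architecture

* Encoder: `depth + 1 = 4` stages of two 3×3 convolutions + ReLU; 2×2 max
  pooling (stride 2) between stages; channel width doubles per stage
  (64, 128, 256, 512 by default). Depth 3 is deliberately one level
  shallower than the classic U-Net to limit overfitting on small crops.
* Feature pyramid: each encoder stage output is projected to a common
  lateral width (default 128) by a 1×1 convolution; a top-down pass
  2×-upsamples the coarser merged map and adds it pixel-by-pixel to the
  next finer lateral map. The merged maps replace the plain skip
  connections.
* Decoder: per step, bilinear 2× upsampling, a 2×2 convolution halving the
  channel count (asymmetric 0/1 padding keeps the spatial size), fusion
  with the pyramid map (channel concatenation by default; 1×1-projected
  addition as an option), then two 3×3 conv + ReLU. A final 1×1
  convolution maps the 64-channel map to 2 class logits, so a 3×H×W input
  yields 2×H×W whenever H and W are divisible by 2^depth (callers pad).
* Decision rule: per-pixel softmax; tumor where its probability exceeds
  0.5; an exact tie goes to background (conservative on false positives).

### A1 detector

The localizer is an anchor-free grid detector: an optional focus
(space-to-depth) slicing halves the resolution losslessly into 4× the
channels, a small convolutional backbone (widths 16/32/64) downsamples to
an 8-pixel cell grid, and a 1×1 head emits, per cell, an objectness logit
plus box center offsets (sigmoid-squashed) and log width/height relative
to the cell stride. A cell is positive when a ground-truth box center
falls in it. Training minimises BCE on objectness (positive cells weighted
50×, since they are well under 1% of the grid) plus squared error on the
box parameters of positive cells (weight 2 each); mosaic augmentation
(four slices composed around a random center, masks and boxes transformed
identically) replaces a training slice with probability 0.5. A
ground-truth "oracle" detector behind the same interface isolates A2 and
the pipeline plumbing in tests.

The detector's score threshold defaults to 0.25, deliberately low: the
cascade unions crops at paste-back, so A2 can reject a spurious crop but
nothing can recover a slice the locator missed.

## Training protocol

Both stages train independently with small-batch SGD. The segmenter uses
the full protocol: learning rate 0.01, momentum 0.9, weight decay 5e-4,
batch size 2, unweighted per-pixel cross-entropy (an optional class-weight
vector exists but is off by default), no schedule, no early stopping. The
detector loss is this package's own construction and uses lr 1e-3 (the
0.01 protocol is unstable for it). Epoch defaults are configurable;
desk-scale experiments use far fewer than the 100-epoch reference
protocol (see below).

A2's training crops are the margin-expanded ground-truth boxes, plus the
crops the *trained* A1 actually produces on the training slices: false
positive detections contribute empty-mask crops (capped at half the
number of positives) so A2 learns to reject them. Convergence is tracked
as tumor-class IoU (Jaccard) on an evaluation set, pooled over pixels,
recorded before training and then once per epoch (or every `eval_every`
iterations).

### Numerical choices

* All arithmetic is float32 (a float64 switch exists for gradient
  verification). Convolution is im2col + BLAS matmul; single-threaded
  runs are bit-reproducible given seeds.
* Weight init is He-normal, except the 1×1 output heads which use a small
  std (0.01) so initial logits are near zero (initial cross-entropy ≈
  ln 2). With He-init heads the default-width segmenter diverges under
  the lr-0.01 momentum protocol.
* Images enter the networks as (v − 127.5)/127.5 ∈ [−1, 1]. Zero-centered
  inputs matter: with all-positive inputs the first layer's gradient
  components share signs and these small from-scratch networks stall.
* **Presentation consistency.** Training packs unevenly sized crops into
  one canvas (the per-dataset maximum, rounded up to the divisibility
  multiple), reflect-padding images and zero-weighting padded pixels in
  the loss. The pyramid-top features are sensitive to that canvas scale,
  so inference pads every crop to the same canvas (recorded on the model
  and in checkpoints) and unpads the prediction. Padding only to the
  divisibility multiple instead makes the segmenter over-paint small
  lesions by an order of magnitude.
* Boxes are 0-based, (row, col) = (y, x), half-open on max edges. Mask
  components use 8-connectivity.
* Dice/Jaccard/precision/recall are undefined on empty denominators and
  raise instead of silently returning 0 or 1; slice-level evaluation
  averages over slices with nonempty ground truth and reports empty-truth
  slices carrying predictions as a separate false-positive-slice count.
  Per-volume pooled aggregation is available by flag.

## Synthetic phantoms

The generator emulates the geometry that makes this segmentation hard,
not CT physics. A volume (default 16×64×64, anisotropic 3×1×1 mm
spacing) contains an organ ellipsoid (intensity 80–120 pre-window units)
on dim background (0–20) with one bright tumor blob (140–180) strictly
inside the organ. The tumor has an in-plane radius drawn from 3–6 px and
a through-plane semi-axis derived from `tumor_slice_fraction`
(default 0.35), so only a minority of slices contain tumor — a sphere of
the same in-plane radius would span most of a thin stack. Boundary
irregularity is a smooth random radial perturbation (low-resolution noise
field upsampled with cubic interpolation, amplitude 0.35 × irregularity,
default 0.3). Additive Gaussian noise (sd 5) covers the volume. The
default abdominal window (level 40, width 400) renders background, organ
and tumor at roughly 13, 166 and 204 grey levels.

What the phantoms do **not** emulate: Hounsfield calibration, partial
volume effects, reconstruction texture, neighbouring organs, hypodense or
heterogeneous lesions, or multi-subtype labels. Passing the end-to-end
phantom study therefore shows the cascade's machinery — detection, crop
geometry, segmentation, paste-back, evaluation — works and is learnable
at realistic contrast and noise; it says nothing about clinical accuracy
on patient CT.

## Desk-scale experiments

The bundled study (`ctcascade.experiments.phantom_study`, also what
`scripts/acceptance.py` runs) trains on 30 phantom volumes and evaluates
on 10 held-out volumes using a narrower segmenter (base width 16, pyramid
width 32) for 15 epochs and the locator for 20 epochs — sizes chosen so
the whole study runs on one CPU core in a few minutes. The architecture,
losses, and protocol are otherwise identical to the full-width defaults.
The ablation harness retrains the cascade per toggle row
({shallow, locator, FPN}); the bundled comparison runs the
full-cascade-vs-no-locator pair on a 12/6 cohort at 8 segmenter epochs,
since every row is a full retraining; the 4-row grid is available through
`pipeline.run_ablation` / the `ablate` CLI command.

## Known limitations

* 2-D slice-wise processing only; no 3-D context across slices.
* The detector is a deliberately small single-scale grid head behind a
  stable interface — the cascade contract is the point, not detector
  internals; it is not a general-purpose object detector.
* Metrics are overlap-based only (no surface distances).
* The train-time canvas rule means a fitted segmenter is calibrated to
  crop scales like those seen in training; radically larger inference
  crops fall back to divisibility padding.
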