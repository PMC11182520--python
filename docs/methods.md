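# Methods

## Problem and model

Delineating organs at risk (OARs) in thoracic CT is hard for two reasons:
organ shape and size change from slice to slice, and several organs (the
esophagus above all) have boundary contrast at or below the acquisition
noise, because the adjacent tissue is of a similar kind.  Plain
encoder–decoder networks tend to over- or under-segment exactly at those
boundaries.

`refineseg` implements an uncertainty-driven, boundary-refined
segmentation pipeline that addresses this in three coupled stages, trained
jointly end to end:

1. **Segmentation.**  A UNet-style encoder feeds three decoders with
   independent weights.  Stage *i* of the encoder applies two Φ blocks
   (3×3 convolution → batch norm → ReLU); stages ≥ 2 finish with 2×2
   max-pooling, and channel counts double per stage from `base_channels`.
   The *main* decoder receives the bottleneck unchanged; auxiliary decoder
   1 receives it after an attention-guided **feature drop** (the `rate`
   fraction of spatial positions with the highest channel-mean activation
   is zeroed across channels), auxiliary decoder 2 after **random noise**
   (multiplicative uniform `x·(1+u)`, `u ~ U(−a, a)`, or additive Gaussian
   `x + N(0, (a·sd(x))²)`).  All decoders share the encoder's skip
   connections, halve channels per step, and end in a 1×1 convolution and
   channel softmax, producing three per-class probability masks.
2. **Uncertainty determination.**  Each mask is binarised by per-pixel
   argmax (ties to the lower class index).  Per class, the union of the
   three binary masks minus their intersection is the *disagreement*
   region: pixels where the decoders do not vote unanimously.  The
   uncertainty map is the disagreement indicator multiplied elementwise by
   the main decoder's *continuous* softmax output, so its magnitude
   carries the main decoder's confidence rather than collapsing to a
   binary flag.
3. **Boundary refinement.**  A second network with two structurally
   identical encoders — one reading the main mask, one the uncertainty
   map — and a single decoder that concatenates matching-resolution skips
   from both encoders.  Each encoder starts with a plain 3×3 convolution
   (no norm/activation), then one Φ block + pooling per stage; the decoder
   applies a Φ block followed by ×2 bilinear upsampling per step and ends
   in a 3×3 convolution with one channel per class.  Its output is a
   **residual** added elementwise to the main mask; with a zeroed final
   convolution the pipeline reduces exactly to the main decoder's argmax.
   The sum is treated as unnormalised class scores: the loss softmax-
   normalises it, and the final label is the per-pixel argmax.

**Loss.**  Every produced mask (main, aux1, aux2, refined) is supervised
by the same hybrid criterion, L = L_CE + L_Dice, summed with equal weight
over masks.  Cross-entropy is the per-pixel mean of −log p(true class)
with the log floored at 1e−12; the dice term is 1 − soft dice (probability-
valued, smoothing ε = 1e−6 in numerator and denominator) averaged over all
classes, background included; per-class weights are a config hook.
Hard (binary) dice is used only for evaluation.

## Design choices where the design was open

* *Feature drop semantics.*  "Feature drop" is implemented as
  attention-guided spatial dropout (zero the top-`rate` channel-mean
  positions, default rate 0.3, seeded tie-breaking) — the perturbation's
  role is to create *informative* decoder disagreement, which dropping
  the most active positions does far more effectively than uniform
  dropout.  Both perturbations act on the encoder bottleneck.
* *Noise semantics.*  Uniformly distributed random noise is multiplicative
  with amplitude 0.3 by default; Gaussian noise is additive and scaled by
  the feature standard deviation so its amplitude parameter is unitless.
  The noise is treated as a constant in the backward pass.
* *Decoder weights are independent.*  Weight sharing would make the three
  decoders agree up to the perturbation and collapse the disagreement
  signal.
* *Upsampling.*  Nearest-neighbour ×2 in the segmentation decoders,
  bilinear ×2 in the refinement decoder.  Only the refinement module's
  upsampling is bilinear by specification of the design; nearest in the
  segmentation path is materially cheaper on CPU and the skip
  concatenation restores high-frequency content.
* *Refinement second encoder.*  The two refinement encoders are parallel:
  each stage reads the same encoder's previous stage (mask encoder from
  mask features, uncertainty encoder from uncertainty features).
* *Refined scores.*  The mask + residual sum can leave [0, 1], so it is
  treated as class scores, softmax-normalised inside the loss, and
  argmaxed for the final decision.
* *Cross-entropy averaging* is per-pixel over the batch.
* *Set algebra on continuous masks* is defined by binarising
  first (argmax), then Boolean algebra per class plane, then weighting by
  the continuous main mask.
* *Perturbations at inference.*  Active whenever an uncertainty map is
  needed (i.e. whenever refinement with uncertainty input runs), with
  per-slice seeds derived from the checkpoint seed, so prediction is
  bit-reproducible.  Disabled when only the main mask is wanted.
* *Hausdorff variant.*  Full (maximum) symmetric Hausdorff distance on
  boundary voxels of the stacked 3-D masks, not HD95.  Units are voxels
  unless a physical spacing is supplied.  Dice of two empty masks is
  defined as 1 (perfect agreement on absence).  Aggregation across
  patients reports mean and *population* variance.
* *Joint training.*  Segmentation and refinement are optimised together
  from scratch under the single summed loss; there is no staging, no
  learning-rate schedule, weight decay or early stopping (all exposed in
  the config with inert defaults).

## Preprocessing

CT volumes are windowed per volume with the radiology convention
`out = clip((HU − (level − width/2)) / width, 0, 1)`; level 30, width 400
(mapping [−170, 230] HU onto [0, 1]) are the defaults used throughout.
Each axial slice is cropped to the largest connected component above 0.05
in windowed units with a 5-pixel margin — this removes the scanner couch
and air — and resized to the working resolution (bilinear image, nearest-
neighbour labels).  A slice with no above-threshold pixel is passed
through unchanged and flagged.  The crop box and original shape are kept
so predictions are mapped back to the original grid before stacking to
3-D for evaluation.  Augmentation (rotation ±15°, crop up to 10% with
zero-padding back) is available but off by default.  The working size is
configurable: 256×256 matches GPU-scale practice, 64×64 is the desk-scale
default.

## Synthetic phantoms: what they emulate, and what they do not

The phantom generator produces air (−1000 HU), an elliptical soft-tissue
body (40 HU) whose axes breathe slightly across slices, and one
superellipse organ per foreground class with per-volume random exponent,
aspect, orientation, and smooth sinusoidal modulation of size, position
and orientation across slices.  Per-slice organ pixel counts are kept
inside the configured size-fraction bounds by a rasterisation correction
loop.  Organ interiors take the configured mean intensity; a 1-pixel rim
is held at body ± the configured boundary-contrast delta.  Additive
Gaussian noise (default sd 15 pseudo-HU) models acquisition noise.

The default conditions pair a **large, high-contrast, lung-like organ**
(mean −760 HU, delta 800 = 53× the noise sd, 5–10 % of the slice) with a
**small, low-contrast, esophagus-like organ** (mean 55 HU, delta 15 =
exactly the noise sd, 1–2.5 % of the slice).  The low-contrast organ is
thus invisible per pixel at SNR 1 — it can only be segmented by spatial
integration, which is the failure mode of interest in real OAR work.

The phantoms deliberately do **not** model: anatomy (no ribs, vertebrae,
mediastinum), partial-volume effects, CT reconstruction artifacts,
inter-patient intensity variation, or more than one connected component
per organ.  Passing the desk-scale tests therefore shows that the
pipeline's mechanics (perturbation-driven disagreement, boundary-
concentrated uncertainty, residual refinement, optimisation) work as
designed — not that clinical-grade accuracy transfers to patient data,
which requires the full-scale datasets and training protocol.

## Numerical and implementation notes

The networks run on a compact reverse-mode automatic-differentiation
engine written on NumPy (`refineseg.nn`): stride-1 convolution as shifted-
slice im2col + GEMM, batch normalisation (biased variance, momentum 0.1,
eps 1e−5), 2×2 max-pooling with argmax scatter, ×2 nearest and bilinear
(half-pixel-centre) upsampling, channel softmax, and Adam (β = 0.9/0.999,
eps 1e−8).  Everything is float32; every layer's gradient is verified
against central finite differences in float64 in the test suite.
Determinism: all randomness flows from seeded `numpy` generators — the
phantom generator is pure given its seed, per-step perturbation seeds are
derived from the global training seed and step index, and per-slice seeds
from the checkpoint seed — so training histories and predictions are
reproducible bit for bit on a fixed platform.

Desk-scale problem sizes used by the test-suite study and the
reproduction script: 10 phantom volumes (8 train / 2 test, volume-level
split) of 20 slices at 64×64, model base 8 / depth 4, Adam lr 1e−3, batch
size 1, 15 epochs; the ablation grid runs at 32×32, base 4 / depth 3,
3+1 volumes of 8 slices, 4 epochs.  These sizes were chosen so the whole
study runs in minutes on one CPU core while leaving every mechanism
(three decoders, uncertainty, refinement) exercised end to end.

## Known limitations

* 2-D slice-wise segmentation only; no 3-D convolutions or pretrained
  backbones.
* The full symmetric Hausdorff distance is sensitive to single outlier
  voxels; HD95 is not provided.
* Batch-norm statistics make training-mode outputs depend on batch
  composition; evaluation uses running averages.
* The Gaussian-noise perturbation's dependence on `sd(x)` is not
  differentiated through.
* DICOM input is out of scope; convert to NIfTI upstream.
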