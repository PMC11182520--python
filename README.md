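# refineseg

Uncertainty-driven, boundary-refined multi-organ CT segmentation,
trainable and testable at desk scale on one CPU.

Delineating organs at risk for radiotherapy planning fails most often at
organ boundaries: organs such as the esophagus have inconsistent shape
and boundary contrast at or below the acquisition noise, because the
surrounding tissue is of a similar kind.  `refineseg` implements a
segmentation pipeline built specifically around that failure mode:

1. a UNet-style **encoder with three decoders** — one main decoder plus
   two auxiliary decoders whose bottleneck input is perturbed (attention-
   guided feature drop; uniform or Gaussian random noise) — produces
   three per-class probability masks per slice;
2. the **disagreement** between the three masks (union minus intersection
   of their argmax binarisations, per class), weighted by the main
   decoder's confidence, yields an **uncertainty map** that localises
   exactly the ambiguous boundary regions;
3. a dual-encoder **residual refinement network** reads the main mask and
   the uncertainty map and predicts an additive correction:
   `refined = mask_main + residual`.

All four masks are supervised jointly with a hybrid loss
`L = L_CE + L_Dice` (cross-entropy plus soft dice), summed over masks,
and optimised with Adam.  Evaluation stacks per-slice predictions back to
3-D and reports per-organ Dice overlap `2|A∩B| / (|A|+|B|)` and symmetric
Hausdorff distance between boundary voxels, as mean ± variance across
patients.

The networks run on a compact NumPy automatic-differentiation engine
shipped with the package (`refineseg.nn`), so there is no GPU or deep-
learning-framework dependency.  A built-in phantom generator produces
synthetic CT volumes — a large high-contrast lung-like organ and a small
esophagus-like organ whose boundary contrast equals the noise level — so
the whole pipeline is trainable and testable in minutes without any
download.  Real volumes are read and written as NIfTI.

## Worked example

```python
import numpy as np
from refineseg import (NetConfig, PhantomConfig, TrainConfig,
                       dice_coefficient, generate_phantom, predict,
                       samples_from_volumes, train)

# 3 phantom volumes: background, lung-like organ (class 1),
# esophagus-like organ (class 2, boundary contrast == noise sd)
vols = [generate_phantom(PhantomConfig(seed=i, n_slices=10)) for i in range(3)]

net = NetConfig(n_classes=3, base_channels=8, depth=4, seed=0)
ckpt, hist = train(samples_from_volumes(vols[:2]), net,
                   TrainConfig(epochs=5, seed=0))
print([round(x, 3) for x in hist.epoch_loss])

labels, unc = predict(ckpt, vols[2].image, return_uncertainty=True)
for c, name in ((1, "lung-like"), (2, "esophagus-like")):
    print(name, round(dice_coefficient(labels == c, vols[2].labels == c), 3))
```

Output (about ten seconds on one CPU core):

```
[5.634, 4.031, 3.228, 2.689, 2.345]
lung-like 0.981
esophagus-like 0.827
```

The per-epoch deep-supervision loss falls steadily, and after five epochs
the held-out volume is already segmented well — with the low-contrast
organ, invisible at single-pixel SNR 1, trailing the high-contrast one as
expected.  `unc` holds the class-summed uncertainty map, which
concentrates along the predicted organ boundaries.

## Command line

```bash
refineseg make-phantom --out-dir data --volumes 10 --seed 0
refineseg train --config run.yaml --manifest data/manifest.json --out model.npz
refineseg predict --checkpoint model.npz --in ct.nii.gz --out seg.nii.gz \
                  --save-uncertainty unc.nii.gz   # add --no-refine to bypass
refineseg evaluate --pred preds/ --gt labels/ --out scores.csv
refineseg ablation --grid grid.yaml --config run.yaml \
                   --train-manifest data/manifest.json \
                   --test-manifest data/manifest.json --out ablation.csv
```

The YAML config mirrors the `NetConfig` / `TrainConfig` / `WindowSpec`
dataclasses; `grid.yaml` is a list of flag overrides (e.g. refinement
on/off, each auxiliary decoder on/off, noise kind) whose rows reproduce
the standard ablation layout.

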