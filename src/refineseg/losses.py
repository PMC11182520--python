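"""Hybrid dice + cross-entropy criterion with four-mask deep supervision.

The training objective applies the same hybrid loss

    L(A, B) = L_CE(A, B) + L_Dice(A, B)

to every produced mask (main, two auxiliaries, refined) and sums the terms
with equal weight.  Cross-entropy is the per-pixel mean of
``-log B[i, gt_i]``; the dice term uses a *soft* (probability-valued) dice
averaged over all classes with a small smoothing epsilon.  The functions
accept either plain ndarrays (evaluation) or autodiff tensors (training);
the return type follows the prediction's type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn

LOG_FLOOR = 1e-12
DICE_EPS = 1e-6


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer label map -> one-hot with the class axis in NCHW position."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(
            f"labels outside [0, {n_classes}): "
            f"[{labels.min()}, {labels.max()}]")
    eye = np.eye(n_classes, dtype=nn.DTYPE)
    oh = eye[labels]                      # (..., H, W, C)
    return np.moveaxis(oh, -1, -3)        # class axis before H, W


def _pred_parts(pred):
    """Return (is_tensor, data array, tensor-or-array handle)."""
    if isinstance(pred, nn.Tensor):
        return True, pred.data, pred
    return False, np.asarray(pred, dtype=np.float64), np.asarray(pred)


def _align(gt: np.ndarray, data: np.ndarray) -> np.ndarray:
    """One-hot gt broadcast to the prediction's (N, C, H, W) layout."""
    n_classes = data.shape[0] if data.ndim == 3 else data.shape[1]
    oh = one_hot(gt, n_classes)
    if oh.shape != data.shape:
        raise ValueError(f"gt shape {np.asarray(gt).shape} does not match "
                         f"prediction shape {data.shape}")
    return oh


def cross_entropy(gt: np.ndarray, pred, floor: float = LOG_FLOOR):
    """Mean over pixels of the negative log-probability of the true class."""
    is_tensor, data, handle = _pred_parts(pred)
    oh = _align(gt, data)
    n_pixels = data.size // (data.shape[0] if data.ndim == 3 else data.shape[1])
    if is_tensor:
        return (nn.log_clipped(handle, floor) * nn.Tensor(oh)).sum() \
            * (-1.0 / n_pixels)
    return float(-(oh * np.log(np.maximum(data, floor))).sum() / n_pixels)


def soft_dice_per_class(gt: np.ndarray, pred, eps: float = DICE_EPS):
    """Per-class soft dice ``(2 sum(p g) + eps) / (sum p + sum g + eps)``.

    Returns a length-C vector (tensor for tensor input).
    """
    is_tensor, data, handle = _pred_parts(pred)
    oh = _align(gt, data)
    axes = (1, 2) if data.ndim == 3 else (0, 2, 3)
    if is_tensor:
        oht = nn.Tensor(oh)
        inter = (handle * oht).sum(axis=axes)
        denom = handle.sum(axis=axes) + nn.Tensor(oh.sum(axis=axes))
        return (2.0 * inter + eps) / (denom + eps)
    inter = (data * oh).sum(axis=axes)
    denom = data.sum(axis=axes) + oh.sum(axis=axes)
    return (2.0 * inter + eps) / (denom + eps)


def dice_loss(gt: np.ndarray, pred, eps: float = DICE_EPS,
              class_weights: np.ndarray | None = None):
    """``1 - soft dice`` averaged over all classes (background included).

    ``class_weights`` (summing to 1) optionally reweights the per-class
    average.
    """
    per_class = soft_dice_per_class(gt, pred, eps)
    n_classes = per_class.shape[0]
    if class_weights is None:
        weights = np.full(n_classes, 1.0 / n_classes, dtype=nn.DTYPE)
    else:
        weights = np.asarray(class_weights, dtype=nn.DTYPE)
        if weights.shape != (n_classes,):
            raise ValueError("class_weights must have one entry per class")
    if isinstance(per_class, nn.Tensor):
        return 1.0 - (per_class * nn.Tensor(weights)).sum()
    return float(1.0 - (per_class * weights).sum())


def hybrid_loss(gt: np.ndarray, pred, class_weights=None):
    """Cross-entropy plus dice loss (equal weights)."""
    ce = cross_entropy(gt, pred)
    dl = dice_loss(gt, pred, class_weights=class_weights)
    return ce + dl


@dataclass
class LossValue:
    """Total deep-supervision loss with a per-mask, per-term breakdown."""

    total: object                       # scalar tensor or float
    per_mask: dict = field(default_factory=dict)   # name -> (ce, dice)

    @property
    def value(self) -> float:
        return self.total.item() if isinstance(self.total, nn.Tensor) \
            else float(self.total)

    def breakdown(self) -> dict[str, float]:
        out = {}
        for name, (ce, dl) in self.per_mask.items():
            out[f"{name}_ce"] = ce.item() if isinstance(ce, nn.Tensor) else float(ce)
            out[f"{name}_dice"] = dl.item() if isinstance(dl, nn.Tensor) else float(dl)
        return out


def total_loss(gt: np.ndarray, mask_main, mask_aux1=None, mask_aux2=None,
               mask_refined=None, class_weights=None) -> LossValue:
    """Unweighted sum of the hybrid losses of all provided masks.

    The refined mask holds unnormalised scores and is softmax-normalised
    here before the hybrid criterion is applied.  Absent masks (``None``)
    simply drop out of the sum, which supports the ablation variants.
    """
    masks = {"main": mask_main}
    if mask_aux1 is not None:
        masks["aux1"] = mask_aux1
    if mask_aux2 is not None:
        masks["aux2"] = mask_aux2
    if mask_refined is not None:
        if isinstance(mask_refined, nn.Tensor):
            masks["refined"] = nn.softmax(mask_refined, axis=-3 if
                                          mask_refined.ndim == 3 else 1)
        else:
            scores = np.asarray(mask_refined, dtype=np.float64)
            axis = 0 if scores.ndim == 3 else 1
            z = scores - scores.max(axis=axis, keepdims=True)
            e = np.exp(z)
            masks["refined"] = e / e.sum(axis=axis, keepdims=True)
    total = None
    per_mask = {}
    for name, mask in masks.items():
        ce = cross_entropy(gt, mask)
        dl = dice_loss(gt, mask, class_weights=class_weights)
        term = ce + dl
        total = term if total is None else total + term
        per_mask[name] = (ce, dl)
    return LossValue(total=total, per_mask=per_mask)
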