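"""Consensus-based uncertainty from the three decoder masks.

A pixel is *uncertain for a class* when the three decoders do not vote
unanimously on that class.  Concretely, the per-class binary masks of the
three decoders are combined by union (all votes) and intersection
(unanimous votes); their difference is the disagreement region, and the
uncertainty map weights that region by the main decoder's softmax
probability so its magnitude carries the main decoder's confidence.

All operations here are pure NumPy Boolean/elementwise algebra on arrays of
shape ``(n_classes, H, W)`` (a leading batch axis is also accepted).
"""

from __future__ import annotations

import numpy as np


def _is_tensor(x) -> bool:
    return not isinstance(x, np.ndarray) and hasattr(x, "backward") \
        and hasattr(x, "data")


def _data(x) -> np.ndarray:
    return x.data if _is_tensor(x) else np.asarray(x)


def binarize(mask) -> np.ndarray:
    """One-hot of the per-pixel argmax over the class axis.

    The class axis is axis 0 for ``(C, H, W)`` input and axis 1 for
    ``(N, C, H, W)``.  Ties break toward the lower class index (argmax
    convention).
    """
    prob = _data(mask)
    axis = 0 if prob.ndim == 3 else 1
    idx = prob.argmax(axis=axis)
    onehot = np.zeros_like(prob, dtype=np.uint8)
    np.put_along_axis(onehot, np.expand_dims(idx, axis), 1, axis=axis)
    return onehot


def _check_shapes(*arrays):
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")


def mask_union(b1, b2, b3) -> np.ndarray:
    """Per-class elementwise OR of the three binary masks (all votes)."""
    b1, b2, b3 = _data(b1), _data(b2), _data(b3)
    _check_shapes(b1, b2, b3)
    return (b1.astype(bool) | b2.astype(bool) | b3.astype(bool)).astype(np.uint8)


def mask_intersection(b1, b2, b3) -> np.ndarray:
    """Per-class elementwise AND of the three binary masks (unanimity)."""
    b1, b2, b3 = _data(b1), _data(b2), _data(b3)
    _check_shapes(b1, b2, b3)
    return (b1.astype(bool) & b2.astype(bool) & b3.astype(bool)).astype(np.uint8)


def disagreement(mask_all, mask_common) -> np.ndarray:
    """Union minus intersection: 1 where the decoders split, else 0."""
    mask_all, mask_common = _data(mask_all), _data(mask_common)
    _check_shapes(mask_all, mask_common)
    if np.any(mask_common > mask_all):
        raise ValueError("mask_common exceeds mask_all; inputs are not "
                         "a union/intersection pair")
    return (mask_all.astype(np.int8) - mask_common.astype(np.int8)).astype(np.uint8)


def uncertainty_map(dis, mask_main):
    """Disagreement indicator weighted by the main decoder's probability.

    ``mask_main`` may be an autodiff tensor, in which case the result is a
    tensor through which gradients flow into the main decoder (the
    disagreement indicator itself is a constant).
    """
    dd = _data(dis)
    if dd.shape != _data(mask_main).shape:
        raise ValueError("disagreement / mask_main shape mismatch")
    if _is_tensor(mask_main):
        from . import nn
        return mask_main * nn.Tensor(dd.astype(nn.DTYPE))
    return np.asarray(mask_main) * dd


def uncertainty_from_masks(mask_main, mask_aux1, mask_aux2):
    """Full pipeline: binarize each mask, then the set algebra above.

    Returns ``(disagreement, uncertainty)``.  ``mask_main`` keeps its type
    (tensor or array) in the weighting step.
    """
    b1 = binarize(mask_main)
    b2 = binarize(mask_aux1)
    b3 = binarize(mask_aux2)
    dis = disagreement(mask_union(b1, b2, b3), mask_intersection(b1, b2, b3))
    return dis, uncertainty_map(dis, mask_main)
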