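"""CT preprocessing: windowing, body cropping, slicing, resizing, augmentation.

The pipeline mirrors standard organ-at-risk practice: intensities are
windowed (level 30, width 400 by default) onto [0, 1] per volume, each
axial slice is cropped to the body region (largest connected above-
threshold component, removing e.g. the scanner couch), resized to the
working resolution, and optionally augmented by rotation/crop/pad.  Every
geometric step records enough information to map predictions back to the
original slice grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

BODY_THRESHOLD = 0.05
BODY_MARGIN = 5


@dataclass(frozen=True)
class WindowSpec:
    """CT display window: ``level`` is the centre, ``width`` the extent.

    With the defaults the interval [-170, 230] HU is mapped affinely onto
    [0, 1]; values outside are clamped.
    """

    level: float = 30.0
    width: float = 400.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("window width must be positive")


def apply_window(volume: np.ndarray, spec: WindowSpec = WindowSpec()
                 ) -> np.ndarray:
    """Affine map of [level - width/2, level + width/2] onto [0, 1]."""
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite intensities")
    lo = spec.level - spec.width / 2.0
    return np.clip((volume - lo) / spec.width, 0.0, 1.0)


@dataclass(frozen=True)
class CropBox:
    """Inclusive-exclusive row/col bounds plus the original slice shape."""

    r0: int
    r1: int
    c0: int
    c1: int
    original_shape: tuple[int, int]
    empty_foreground: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)


def crop_body(slice_img: np.ndarray, labels: np.ndarray | None = None,
              threshold: float = BODY_THRESHOLD, margin: int = BODY_MARGIN):
    """Crop a windowed slice to the largest above-threshold component.

    Returns ``(cropped_image, cropped_labels, CropBox)``; ``cropped_labels``
    is ``None`` when no labels are given.  An entirely sub-threshold slice
    is returned unchanged with ``empty_foreground=True``.
    """
    img = np.asarray(slice_img)
    h, w = img.shape
    fg = img > threshold
    if not fg.any():
        box = CropBox(0, h, 0, w, (h, w), empty_foreground=True)
        lab = None if labels is None else np.asarray(labels)
        return img, lab, box
    comp, n = ndimage.label(fg)
    largest = np.argmax(ndimage.sum_labels(fg, comp, range(1, n + 1))) + 1
    rows, cols = np.nonzero(comp == largest)
    r0 = max(int(rows.min()) - margin, 0)
    r1 = min(int(rows.max()) + 1 + margin, h)
    c0 = max(int(cols.min()) - margin, 0)
    c1 = min(int(cols.max()) + 1 + margin, w)
    box = CropBox(r0, r1, c0, c1, (h, w))
    lab = None if labels is None else np.asarray(labels)[r0:r1, c0:c1]
    return img[r0:r1, c0:c1], lab, box


def uncrop_labels(labels: np.ndarray, box: CropBox,
                  fill: int = 0) -> np.ndarray:
    """Paste cropped-space labels back onto the original slice grid."""
    labels = np.asarray(labels)
    if labels.shape != box.shape:
        raise ValueError(f"labels {labels.shape} do not match crop box "
                         f"{box.shape}")
    out = np.full(box.original_shape, fill, dtype=labels.dtype)
    out[box.r0:box.r1, box.c0:box.c1] = labels
    return out


def resize_pair(image: np.ndarray, labels: np.ndarray | None,
                target: tuple[int, int]):
    """Resize image (linear) and labels (nearest neighbour) together.

    Nearest-neighbour resampling guarantees the label set never grows.
    Resizing to the input shape is an exact identity.
    """
    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError("target size must be positive")
    image = np.asarray(image, dtype=np.float64)
    if image.shape == (th, tw):
        out_img = image.copy()
    else:
        out_img = _sk_resize(image, (th, tw), order=1, mode="edge",
                             anti_aliasing=False, preserve_range=True)
    out_lab = None
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape == (th, tw):
            out_lab = labels.copy()
        else:
            out_lab = _sk_resize(labels, (th, tw), order=0, mode="edge",
                                 anti_aliasing=False,
                                 preserve_range=True).astype(labels.dtype)
    return out_img, out_lab


@dataclass
class SliceSample:
    """One training unit: a windowed [0, 1] slice with aligned labels."""

    image: np.ndarray
    labels: np.ndarray
    volume_id: int = 0
    slice_index: int = 0
    box: CropBox | None = None

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must share a shape")


def rotate_pair(image: np.ndarray, labels: np.ndarray, angle: float):
    """Rotate image (bilinear) and labels (nearest) by ``angle`` degrees,
    about the slice centre, keeping the shape."""
    if abs(angle) < 1e-9:
        return image.copy(), labels.copy()
    img = ndimage.rotate(image, angle, reshape=False, order=1,
                         mode="constant", cval=0.0)
    lab = ndimage.rotate(labels, angle, reshape=False, order=0,
                         mode="constant", cval=0)
    return np.clip(img, 0.0, 1.0), lab


def augment(sample: SliceSample, seed: int, max_rotation: float = 15.0,
            max_crop_frac: float = 0.10) -> SliceSample:
    """Random rotation plus random crop/pad, identical on image and labels.

    The rotation resamples the image bilinearly and the labels by nearest
    neighbour; cropping removes a random margin and zero-pads back to the
    original size, so no new label values can appear.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    img, lab = sample.image, sample.labels
    h, w = img.shape
    angle = float(rng.uniform(-max_rotation, max_rotation))
    img, lab = rotate_pair(img, lab, angle)
    crop_frac = float(rng.uniform(0.0, max_crop_frac))
    dh = int(round(crop_frac * h))
    dw = int(round(crop_frac * w))
    if dh or dw:
        r0 = int(rng.integers(0, dh + 1))
        c0 = int(rng.integers(0, dw + 1))
        img_c = img[r0:h - (dh - r0), c0:w - (dw - c0)]
        lab_c = lab[r0:h - (dh - r0), c0:w - (dw - c0)]
        img = np.zeros_like(img)
        lab = np.zeros_like(lab)
        img[r0:r0 + img_c.shape[0], c0:c0 + img_c.shape[1]] = img_c
        lab[r0:r0 + lab_c.shape[0], c0:c0 + lab_c.shape[1]] = lab_c
    return SliceSample(image=img, labels=lab, volume_id=sample.volume_id,
                       slice_index=sample.slice_index, box=sample.box)


def preprocess_volume(image: np.ndarray, labels: np.ndarray | None,
                      window: WindowSpec = WindowSpec(),
                      work_size: tuple[int, int] = (64, 64),
                      volume_id: int = 0) -> list[SliceSample]:
    """Window per volume, crop and resize per axial slice.

    Returns one :class:`SliceSample` per slice (labels all-zero when no
    label volume is given) with the crop geometry attached for inverse
    mapping at prediction time.
    """
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {image.shape}")
    win = apply_window(image, window)
    samples = []
    for s in range(win.shape[0]):
        lab_s = None if labels is None else np.asarray(labels)[s]
        img_c, lab_c, box = crop_body(win[s], lab_s)
        if lab_c is None:
            lab_c = np.zeros_like(img_c, dtype=np.int64)
        img_r, lab_r = resize_pair(img_c, lab_c, work_size)
        samples.append(SliceSample(image=img_r, labels=lab_r.astype(np.int64),
                                   volume_id=volume_id, slice_index=s,
                                   box=box))
    return samples


def postprocess_labels(labels: np.ndarray, box: CropBox) -> np.ndarray:
    """Inverse of crop+resize: map working-size labels to the original grid."""
    lab = np.asarray(labels)
    _, lab_resized = resize_pair(lab.astype(np.float64), lab, box.shape)
    return uncrop_labels(lab_resized, box)


def postprocess_map(values: np.ndarray, box: CropBox) -> np.ndarray:
    """Same inverse mapping for a continuous per-pixel map (bilinear)."""
    img, _ = resize_pair(np.asarray(values, dtype=np.float64), None,
                         box.shape)
    out = np.zeros(box.original_shape, dtype=np.float64)
    out[box.r0:box.r1, box.c0:box.c1] = img
    return out
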