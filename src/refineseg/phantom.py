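"""Synthetic CT phantoms with multi-organ ground truth.

The generator emulates, at desk scale, the two properties of thoracic CT
that make organ-at-risk segmentation hard: organs whose shape and size vary
from slice to slice, and organs whose boundary contrast against the
surrounding soft tissue is at or below the acquisition noise level.  Each
volume contains an air background (≈ -1000 HU), an elliptical soft-tissue
"body" (≈ 40 HU), and one superellipse-shaped organ per foreground class
whose axes, exponent, orientation and position drift smoothly across
slices.  The default specification pairs a large high-contrast, lung-like
organ with a small, esophagus-like organ whose contrast against the body
equals the noise standard deviation.

All randomness flows from one seeded generator per call, so volumes are
bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma_fn

AIR_HU = -1000.0
BODY_HU = 40.0
COUCH_HU = 150.0


@dataclass
class OrganSpec:
    """One foreground organ: intensity, contrast, size and shape jitter.

    ``mean_hu`` fills the organ interior; the 1-pixel boundary band is held
    at ``body ± boundary_delta`` so the configured delta is exactly the
    contrast an observer sees at the organ edge.  ``size_frac`` bounds the
    per-slice pixel count as a fraction of the slice area and
    ``shape_jitter`` (0..1) scales the slice-to-slice modulation of size,
    aspect and position.  ``anchor`` places the organ relative to the body
    centre, in fractions of the slice height/width.
    """

    name: str
    mean_hu: float
    boundary_delta: float
    size_frac: tuple[float, float]
    shape_jitter: float
    anchor: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        lo, hi = self.size_frac
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"size fractions must satisfy 0 < lo < hi < 1, "
                             f"got {self.size_frac}")
        if self.boundary_delta < 0:
            raise ValueError("boundary_delta must be >= 0")
        if not 0.0 <= self.shape_jitter <= 1.0:
            raise ValueError("shape_jitter must be in [0, 1]")


def default_organ_specs() -> list[OrganSpec]:
    return [
        OrganSpec(name="lung_like", mean_hu=-760.0, boundary_delta=800.0,
                  size_frac=(0.05, 0.10), shape_jitter=0.15,
                  anchor=(0.0, -0.18)),
        OrganSpec(name="esophagus_like", mean_hu=55.0, boundary_delta=15.0,
                  size_frac=(0.01, 0.025), shape_jitter=0.25,
                  anchor=(0.05, 0.17)),
    ]


@dataclass
class PhantomConfig:
    """Settings of the phantom generator; defaults are the desk-scale study
    conditions (64 x 64 slices, one lung-like and one esophagus-like organ,
    15 pseudo-HU acquisition noise)."""

    n_slices: int = 20
    height: int = 64
    width: int = 64
    n_classes: int = 3
    organ_specs: list[OrganSpec] = field(default_factory=default_organ_specs)
    noise_sd: float = 15.0
    seed: int = 0
    include_couch: bool = False
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)

    def __post_init__(self):
        if self.n_slices < 1 or self.height < 8 or self.width < 8:
            raise ValueError("n_slices must be >= 1 and height/width >= 8")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2 (background + organs)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if len(self.organ_specs) != self.n_classes - 1:
            raise ValueError(
                f"need exactly {self.n_classes - 1} organ specs for "
                f"{self.n_classes} classes, got {len(self.organ_specs)}")
        # organs must be able to coexist inside the body without overlap;
        # the body ellipse covers ~0.58 of the slice
        total_max = sum(spec.size_frac[1] for spec in self.organ_specs)
        if total_max > 0.35:
            raise ValueError(
                f"organ size fractions cannot coexist: max fractions sum to "
                f"{total_max:.2f} > 0.35 of the slice")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["organ_specs"] = [asdict(s) for s in self.organ_specs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        specs = [OrganSpec(**{**s, "size_frac": tuple(s["size_frac"]),
                              "anchor": tuple(s["anchor"])})
                 for s in d.pop("organ_specs")]
        d["spacing"] = tuple(d.get("spacing", (2.5, 1.0, 1.0)))
        return cls(organ_specs=specs, **d)


@dataclass
class PhantomVolume:
    """Image plus aligned integer label volume (slices x H x W)."""

    image: np.ndarray
    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        if self.image.shape != self.labels.shape:
            raise ValueError("image and labels must have identical shape")


def _superellipse_area_factor(p: float) -> float:
    """Area of |u/a|^p + |v/b|^p <= 1 equals factor * a * b."""
    return 4.0 * _gamma_fn(1 + 1 / p) ** 2 / _gamma_fn(1 + 2 / p)


def _rasterize(h: int, w: int, cy: float, cx: float, a: float, b: float,
               p: float, theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    dy = yy - cy
    dx = xx - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    with np.errstate(invalid="ignore"):
        r = np.abs(u / a) ** p + np.abs(v / b) ** p
    return r <= 1.0


def _fit_organ(h, w, cy, cx, target, p, ratio, theta, lo_count, hi_count,
               allowed):
    """Rasterize a superellipse of roughly ``target`` pixels, correcting the
    scale until the count (within ``allowed``) lies in [lo, hi]."""
    factor = _superellipse_area_factor(p)
    ab = target / factor
    a = math.sqrt(ab * ratio)
    b = math.sqrt(ab / ratio)
    mask = _rasterize(h, w, cy, cx, a, b, p, theta) & allowed
    for _ in range(6):
        count = int(mask.sum())
        if lo_count <= count <= hi_count:
            break
        goal = 0.5 * (lo_count + hi_count)
        scale = math.sqrt(goal / max(count, 1))
        a *= scale
        b *= scale
        mask = _rasterize(h, w, cy, cx, a, b, p, theta) & allowed
    return mask


def generate_phantom(config: PhantomConfig) -> PhantomVolume:
    """Generate one phantom volume; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    h, w, n_slices = config.height, config.width, config.n_slices
    n_px = h * w
    image = np.full((n_slices, h, w), AIR_HU, dtype=np.float64)
    labels = np.zeros((n_slices, h, w), dtype=np.int64)

    body_ry = 0.44 * h
    body_rx = 0.42 * w
    body_phase = rng.uniform(0, 2 * math.pi, 2)

    # per-organ smooth modulation: random phases / frequencies per volume
    organ_params = []
    for spec in config.organ_specs:
        lo, hi = spec.size_frac
        margin = 0.2 * (hi - lo)
        base = rng.uniform(lo + margin + 0.15 * (hi - lo),
                           hi - margin - 0.15 * (hi - lo))
        organ_params.append({
            "base_frac": base,
            "freq": rng.uniform(0.5, 1.5, 3),
            "phase": rng.uniform(0, 2 * math.pi, 3),
            "p": rng.uniform(1.7, 3.0),
            "ratio": rng.uniform(0.8, 1.25),
            "theta0": rng.uniform(0, math.pi),
        })

    for s in range(n_slices):
        t = s / max(n_slices - 1, 1)
        ry = body_ry * (1 + 0.04 * math.sin(2 * math.pi * t + body_phase[0]))
        rx = body_rx * (1 + 0.04 * math.sin(2 * math.pi * t + body_phase[1]))
        body = _rasterize(h, w, h / 2, w / 2, ry, rx, 2.0, math.pi / 2)
        image[s][body] = BODY_HU
        interior = ndimage.binary_erosion(body, iterations=2,
                                          border_value=0)
        occupied = np.zeros((h, w), dtype=bool)
        centroids: list[tuple[float, float]] = []
        for cls, (spec, par) in enumerate(
                zip(config.organ_specs, organ_params), start=1):
            lo, hi = spec.size_frac
            jit = spec.shape_jitter
            frac = par["base_frac"] * (
                1 + 0.6 * jit * math.sin(
                    2 * math.pi * par["freq"][0] * t + par["phase"][0]))
            frac = min(max(frac, lo + 0.1 * (hi - lo)), hi - 0.1 * (hi - lo))
            target = frac * n_px
            cy = h / 2 + spec.anchor[0] * h + 1.5 * jit * math.sin(
                2 * math.pi * par["freq"][1] * t + par["phase"][1]) * 2
            cx = w / 2 + spec.anchor[1] * w + 1.5 * jit * math.sin(
                2 * math.pi * par["freq"][2] * t + par["phase"][2]) * 2
            theta = par["theta0"] + 0.4 * jit * math.sin(2 * math.pi * t)
            allowed = interior & ~occupied
            mask = None
            for _ in range(8):
                mask = _fit_organ(h, w, cy, cx, target, par["p"],
                                  par["ratio"], theta,
                                  math.ceil(lo * n_px),
                                  math.floor(hi * n_px), allowed)
                if mask.sum() >= math.ceil(lo * n_px):
                    break
                # crowded: move away from previously placed organs
                if centroids:
                    oy, ox = centroids[-1]
                    norm = math.hypot(cy - oy, cx - ox) or 1.0
                    cy += 2.0 * (cy - oy) / norm
                    cx += 2.0 * (cx - ox) / norm
                else:  # squeezed by the body wall: move towards centre
                    cy += 0.2 * (h / 2 - cy)
                    cx += 0.2 * (w / 2 - cx)
            if not mask.any():
                raise ValueError(
                    f"could not place organ {spec.name!r} in slice {s}; "
                    f"size fractions cannot coexist")
            occupied |= mask
            ys, xs = np.nonzero(mask)
            centroids.append((float(ys.mean()), float(xs.mean())))
            labels[s][mask] = cls
            # interior at the configured mean, 1-px rim at body +- delta
            rim_sign = 1.0 if spec.mean_hu >= BODY_HU else -1.0
            rim_hu = BODY_HU + rim_sign * min(abs(spec.mean_hu - BODY_HU),
                                              spec.boundary_delta)
            inner = ndimage.binary_erosion(mask, border_value=0)
            image[s][mask] = rim_hu
            image[s][inner] = spec.mean_hu
        if config.include_couch:
            row = int(0.94 * h)
            couch = np.zeros((h, w), dtype=bool)
            couch[row:row + 2, int(0.2 * w):int(0.8 * w)] = True
            couch &= ~body
            image[s][couch] = COUCH_HU

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, image.shape)
    return PhantomVolume(image=image, labels=labels, spacing=config.spacing)


def phantom_train_test_split(volume_count: int, fraction: float,
                             seed: int) -> tuple[list[int], list[int]]:
    """Disjoint, exhaustive volume-level split (never slice-level)."""
    if volume_count < 2:
        raise ValueError("need at least 2 volumes to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(volume_count)
    n_train = int(round(fraction * volume_count))
    n_train = min(max(n_train, 1), volume_count - 1)
    return sorted(int(i) for i in order[:n_train]), \
        sorted(int(i) for i in order[n_train:])
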