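"""Encoder with one main and two perturbed auxiliary decoders.

The segmentation module is a UNet-style encoder/decoder.  A single encoder
feeds three decoders with independent weights: the *main* decoder receives
the bottleneck unchanged, auxiliary decoder 1 receives it after an
attention-guided *feature drop*, and auxiliary decoder 2 after a random
*noise* perturbation (uniform multiplicative by default, Gaussian additive
as an alternative).  All three decoders share the encoder's skip
connections.  Each decoder ends in a 1x1 convolution to ``n_classes``
channels followed by a channel softmax, so each output is a per-class
probability mask whose channels sum to one at every pixel.

The perturbations exist to make the auxiliary decoders *disagree* with the
main decoder exactly where the input is ambiguous — typically at low
contrast organ boundaries — which downstream modules turn into an
uncertainty map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

NOISE_KINDS = ("uniform", "gaussian")


@dataclass
class NetConfig:
    """Architecture and perturbation settings.

    ``base_channels`` is the channel count of the first encoder stage and is
    doubled at every stage (64 suits full-scale training; 8 is a practical
    desk-scale default).  ``depth`` counts encoder stages, so ``depth - 1``
    poolings occur.  ``feature_drop_rate`` is the fraction of spatial
    positions zeroed in the feature-drop perturbation and
    ``noise_amplitude`` scales the noise perturbation.
    """

    n_classes: int = 3
    base_channels: int = 8
    depth: int = 5
    noise_kind: str = "uniform"
    noise_amplitude: float = 0.3
    feature_drop_rate: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.noise_kind not in NOISE_KINDS:
            raise ValueError(f"noise_kind must be one of {NOISE_KINDS}")
        if not 0.0 < self.feature_drop_rate < 1.0:
            raise ValueError("feature_drop_rate must be in (0, 1)")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")

    def stage_channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]

    def to_dict(self) -> dict:
        return asdict(self)


class PhiBlock(nn.Module):
    """3x3 convolution -> batch norm -> ReLU, spatial size preserved."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return nn.relu(self.bn(self.conv(x)))


class Encoder(nn.Module):
    """Stage i applies two Phi blocks; stages >= 2 then 2x2 max-pool.

    Stage outputs form the feature pyramid: with ``base_channels`` b the
    stage i output has b*2^(i-1) channels, and the spatial size halves at
    every stage after the first.
    """

    def __init__(self, cfg: NetConfig, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        chans = cfg.stage_channels()
        self.blocks = []
        prev = in_channels
        for c in chans:
            self.blocks.append(PhiBlock(prev, c, rng))
            self.blocks.append(PhiBlock(c, c, rng))
            prev = c
        self.depth = cfg.depth

    def __call__(self, x: nn.Tensor) -> list[nn.Tensor]:
        feats: list[nn.Tensor] = []
        h = x
        for i in range(self.depth):
            h = self.blocks[2 * i](h)
            h = self.blocks[2 * i + 1](h)
            if i >= 1:
                h = nn.max_pool2x(h)
            feats.append(h)
        return feats


class Decoder(nn.Module):
    """Upsample, concatenate the matching encoder skip, two Phi blocks.

    The channel count halves at every step; a final 1x1 convolution maps to
    ``n_classes`` logits at full resolution.
    """

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.stage_channels()
        self.steps = []
        for i in range(1, cfg.depth):
            skip_c = chans[cfg.depth - 1 - i]
            in_c = chans[cfg.depth - i] + skip_c
            out_c = chans[cfg.depth - 1 - i]
            self.steps.append(PhiBlock(in_c, out_c, rng))
            self.steps.append(PhiBlock(out_c, out_c, rng))
        self.head = nn.Conv2d(chans[0], cfg.n_classes, 1, rng=rng)
        self.depth = cfg.depth

    def __call__(self, pyramid: list[nn.Tensor],
                 bottleneck: nn.Tensor) -> nn.Tensor:
        if bottleneck.shape != pyramid[-1].shape:
            raise ValueError("bottleneck does not match the deepest stage")
        h = bottleneck
        for i in range(1, self.depth):
            h = nn.upsample_nearest2x(h)
            skip = pyramid[self.depth - 1 - i]
            h = nn.concat([h, skip], axis=1)
            h = self.steps[2 * (i - 1)](h)
            h = self.steps[2 * (i - 1) + 1](h)
        return self.head(h)


def perturb_feature_drop(x, rate: float, seed: int):
    """Zero the ``rate`` fraction of spatial positions with the highest
    channel-mean activation, across all channels (attention-guided drop).

    Ties (e.g. constant feature maps) are broken by a seeded random key, so
    the dropped set is deterministic given the seed.  Accepts a Tensor or an
    ndarray; the drop mask is a constant with respect to the input.
    """
    if not 0.0 < rate < 1.0:
        raise ValueError("rate must be in (0, 1)")
    data = x.data if isinstance(x, nn.Tensor) else np.asarray(x)
    n, c, h, w = data.shape
    k = int(round(rate * h * w))
    rng = np.random.default_rng(seed)
    mask = np.ones((n, 1, h, w), dtype=data.dtype)
    for b in range(n):
        score = data[b].mean(axis=0).ravel()
        tiebreak = rng.random(score.size)
        order = np.lexsort((tiebreak, -score))  # highest score first
        drop = order[:k]
        flat = mask[b, 0].ravel()
        flat[drop] = 0.0
    if isinstance(x, nn.Tensor):
        return x * nn.Tensor(mask)
    return data * mask


def perturb_noise(x, kind: str, amplitude: float, seed: int):
    """Perturb features with random noise.

    ``uniform``: multiplicative, ``x * (1 + u)`` with ``u ~ U(-a, a)``
    elementwise (uniformly distributed random noise).  ``gaussian``:
    additive, ``x + g`` with ``g ~ N(0, (a * sd(x))^2)``.  Deterministic
    given the seed; the noise is a constant with respect to the input.
    """
    if kind not in NOISE_KINDS:
        raise ValueError(f"kind must be one of {NOISE_KINDS}")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    data = x.data if isinstance(x, nn.Tensor) else np.asarray(x)
    if amplitude == 0:
        return x
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        factor = (1.0 + rng.uniform(-amplitude, amplitude,
                                    data.shape)).astype(data.dtype)
        if isinstance(x, nn.Tensor):
            return x * nn.Tensor(factor)
        return data * factor
    sd = float(data.std())
    noise = rng.normal(0.0, amplitude * sd, data.shape).astype(data.dtype)
    if isinstance(x, nn.Tensor):
        return x + nn.Tensor(noise)
    return data + noise


class SegmentationNet(nn.Module):
    """One encoder, three decoders (main, feature-drop aux, noise aux)."""

    def __init__(self, cfg: NetConfig, use_aux1: bool = True,
                 use_aux2: bool = True):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = Encoder(cfg, rng)
        self.dec_main = Decoder(cfg, rng)
        self.dec_aux1 = Decoder(cfg, rng) if use_aux1 else None
        self.dec_aux2 = Decoder(cfg, rng) if use_aux2 else None

    def encode(self, image: nn.Tensor) -> list[nn.Tensor]:
        n, c, h, w = nn.as_tensor(image).shape
        div = 2 ** (self.cfg.depth - 1)
        if h % div or w % div:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by {div} "
                f"(depth {self.cfg.depth})")
        return self.encoder(nn.as_tensor(image))

    def segment(self, image, perturb: bool = True, seed: int = 0):
        """Return ``(mask_main, mask_aux1, mask_aux2)`` probability masks.

        Auxiliary masks are ``None`` when the corresponding decoder is
        absent.  With ``perturb=False`` (or zero perturbation settings) all
        bottlenecks are identical.
        """
        pyramid = self.encode(image)
        bottleneck = pyramid[-1]
        mask_main = nn.softmax(self.dec_main(pyramid, bottleneck), axis=1)
        mask_aux1 = mask_aux2 = None
        if self.dec_aux1 is not None:
            b1 = perturb_feature_drop(
                bottleneck, self.cfg.feature_drop_rate,
                seed) if perturb else bottleneck
            mask_aux1 = nn.softmax(self.dec_aux1(pyramid, b1), axis=1)
        if self.dec_aux2 is not None:
            b2 = perturb_noise(
                bottleneck, self.cfg.noise_kind, self.cfg.noise_amplitude,
                seed + 1) if perturb else bottleneck
            mask_aux2 = nn.softmax(self.dec_aux2(pyramid, b2), axis=1)
        return mask_main, mask_aux1, mask_aux2

    def __call__(self, image, perturb: bool = True, seed: int = 0):
        return self.segment(image, perturb=perturb, seed=seed)
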