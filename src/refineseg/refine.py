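"""Residual boundary refinement driven by the uncertainty map.

The refinement network has two parallel encoders with identical layout —
one consumes the main probability mask, the other the uncertainty map —
and a single decoder that concatenates matching-resolution skip
connections from both encoders.  Its output is a per-class *residual*
added elementwise to the main mask:

    refined = mask_main + residual

so a zeroed final convolution leaves the main mask untouched.  The refined
mask is a map of unnormalised class scores; the training loss softmax-
normalises it before applying the hybrid criterion, and the final label
decision is a per-pixel argmax.

Each encoder starts with a plain 3x3 convolution (no norm/activation),
then one Phi block (conv/BN/ReLU) followed by 2x2 max-pooling per stage.
The decoder applies a Phi block then x2 bilinear upsampling per step, with
a final Phi block and 3x3 convolution to ``n_classes`` channels.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .segnet import NetConfig, PhiBlock


class RefinementEncoder(nn.Module):
    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        super().__init__()
        chans = cfg.stage_channels()
        self.stem = nn.Conv2d(cfg.n_classes, chans[0], 3, rng=rng)
        self.blocks = [PhiBlock(chans[i - 1], chans[i], rng)
                       for i in range(1, cfg.depth)]

    def __call__(self, x: nn.Tensor) -> list[nn.Tensor]:
        feats = [self.stem(x)]
        h = feats[0]
        for block in self.blocks:
            h = nn.max_pool2x(block(h))
            feats.append(h)
        return feats


class RefinementDecoder(nn.Module):
    """Phi + bilinear x2 per step, dual (or single) encoder skips."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator,
                 dual: bool = True):
        super().__init__()
        chans = cfg.stage_channels()
        mult = 2 if dual else 1
        self.steps = []
        # step 0 consumes the deepest skips; steps 1..depth-2 also take the
        # previous decoder output
        self.steps.append(PhiBlock(mult * chans[-1], chans[-1], rng))
        for i in range(1, cfg.depth - 1):
            skip_c = chans[cfg.depth - 1 - i]
            in_c = chans[cfg.depth - i] + mult * skip_c
            self.steps.append(PhiBlock(in_c, skip_c, rng))
        self.final_phi = PhiBlock(chans[1], chans[0], rng)
        self.head = nn.Conv2d(chans[0], cfg.n_classes, 3, rng=rng)
        self.depth = cfg.depth
        self.dual = dual

    def __call__(self, y_feats: list[nn.Tensor],
                 z_feats: list[nn.Tensor] | None) -> nn.Tensor:
        def skips(i):
            s = [y_feats[i]]
            if self.dual:
                s.append(z_feats[i])
            return s

        h = nn.concat(skips(self.depth - 1), axis=1) if self.dual \
            else y_feats[self.depth - 1]
        h = nn.upsample_bilinear2x(self.steps[0](h))
        for i in range(1, self.depth - 1):
            h = nn.concat([h] + skips(self.depth - 1 - i), axis=1)
            h = nn.upsample_bilinear2x(self.steps[i](h))
        return self.head(self.final_phi(h))


class RefinementNet(nn.Module):
    """Dual-encoder/single-decoder residual refinement module."""

    def __init__(self, cfg: NetConfig, use_uncertainty_input: bool = True):
        super().__init__()
        self.cfg = cfg
        self.use_uncertainty_input = use_uncertainty_input
        rng = np.random.default_rng(cfg.seed + 104729)
        self.enc_mask = RefinementEncoder(cfg, rng)
        self.enc_unc = RefinementEncoder(cfg, rng) \
            if use_uncertainty_input else None
        self.decoder = RefinementDecoder(cfg, rng,
                                         dual=use_uncertainty_input)

    def refine(self, mask_main, unc=None):
        """Return ``(residual, refined)``, both ``N x C x H x W`` tensors."""
        mask_main = nn.as_tensor(mask_main)
        if mask_main.shape[1] != self.cfg.n_classes:
            raise ValueError("mask_main channel count != n_classes")
        y_feats = self.enc_mask(mask_main)
        z_feats = None
        if self.use_uncertainty_input:
            if unc is None:
                raise ValueError("this refinement net needs an uncertainty map")
            unc = nn.as_tensor(unc)
            if unc.shape != mask_main.shape:
                raise ValueError("uncertainty / mask_main shape mismatch")
            z_feats = self.enc_unc(unc)
        residual = self.decoder(y_feats, z_feats)
        refined = mask_main + residual
        return residual, refined

    def __call__(self, mask_main, unc=None):
        return self.refine(mask_main, unc)

    def zero_head(self) -> None:
        """Zero the final convolution so the residual is identically zero."""
        self.decoder.head.weight.data[:] = 0
        self.decoder.head.bias.data[:] = 0


def refined_to_labels(refined) -> np.ndarray:
    """Per-pixel argmax over class scores; ties go to the lower index."""
    data = refined.data if isinstance(refined, nn.Tensor) \
        else np.asarray(refined)
    if not np.all(np.isfinite(data)):
        raise ValueError("refined mask contains non-finite scores")
    axis = 0 if data.ndim == 3 else 1
    return data.argmax(axis=axis).astype(np.int64)
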