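"""End-to-end training loop, checkpointing, prediction and ablations.

Training optimises the segmentation decoders and the refinement network
jointly with Adam on the summed hybrid loss of every produced mask (deep
supervision).  Per-step perturbation seeds derive from the global seed and
the step index, so runs are reproducible.  Checkpoints embed both the
network and training configurations together with the preprocessing
settings, so prediction needs nothing but the checkpoint and a raw volume.

Ablation switches mirror the model's component structure: each auxiliary
decoder, the uncertainty input of the refinement net, and the refinement
net itself can be disabled, which reduces the system down to a plain
UNet-style encoder/decoder.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import losses, metrics, nn
from .preprocess import SliceSample, WindowSpec, postprocess_labels, \
    postprocess_map, preprocess_volume
from .refine import RefinementNet, refined_to_labels
from .segnet import NetConfig, SegmentationNet
from .uncertainty import binarize, uncertainty_from_masks


class ConfigError(ValueError):
    """Inconsistent training/ablation flag combination."""


@dataclass
class TrainConfig:
    """Optimisation settings and ablation flags.

    Full-scale defaults are Adam, 200 epochs, learning rate 1e-3, batch
    size 1; desk-scale runs shorten the epoch count.  ``use_*`` flags
    select the model variant (all on = the full model).
    """

    epochs: int = 200
    learning_rate: float = 1e-3
    batch_size: int = 1
    optimizer: str = "adam"
    seed: int = 0
    use_refinement: bool = True
    use_uncertainty_input: bool = True
    use_aux1: bool = True
    use_aux2: bool = True
    augment: bool = False

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("epochs, batch_size and learning_rate must be "
                              "positive")
        if self.optimizer != "adam":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.use_uncertainty_input and self.use_refinement \
                and not (self.use_aux1 or self.use_aux2):
            raise ConfigError("uncertainty input requires at least one "
                              "auxiliary decoder")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    """Per-epoch loss means; one entry per completed epoch."""

    epoch_loss: list[float] = field(default_factory=list)
    epoch_terms: list[dict[str, float]] = field(default_factory=list)
    steps_per_epoch: list[int] = field(default_factory=list)

    def __len__(self):
        return len(self.epoch_loss)

    def to_csv(self, path) -> None:
        keys = sorted({k for terms in self.epoch_terms for k in terms})
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "total", *keys])
            for i, (total, terms) in enumerate(
                    zip(self.epoch_loss, self.epoch_terms), start=1):
                writer.writerow([i, total, *[terms.get(k, "") for k in keys]])


class Model:
    """Segmentation net plus (optionally) the refinement net."""

    def __init__(self, net_cfg: NetConfig, train_cfg: TrainConfig):
        self.net_cfg = net_cfg
        self.train_cfg = train_cfg
        self.seg = SegmentationNet(net_cfg, use_aux1=train_cfg.use_aux1,
                                   use_aux2=train_cfg.use_aux2)
        self.ref = RefinementNet(
            net_cfg, use_uncertainty_input=train_cfg.use_uncertainty_input) \
            if train_cfg.use_refinement else None

    # -- mode / parameters ---------------------------------------------------
    def parameters(self):
        params = self.seg.parameters()
        if self.ref is not None:
            params += self.ref.parameters()
        return params

    def named_parameters(self):
        named = dict(self.seg.named_parameters())
        if self.ref is not None:
            named.update({f"ref.{k}": v
                          for k, v in self.ref.named_parameters()})
        return named

    def train(self):
        self.seg.train()
        if self.ref is not None:
            self.ref.train()

    def eval(self):
        self.seg.eval()
        if self.ref is not None:
            self.ref.eval()

    # -- forward -------------------------------------------------------------
    def forward_loss(self, image: np.ndarray, gt: np.ndarray,
                     step_seed: int) -> losses.LossValue:
        """Full forward pass on one batch, returning the supervised loss."""
        x = nn.Tensor(image)
        main, aux1, aux2 = self.seg.segment(x, perturb=True, seed=step_seed)
        refined = None
        if self.ref is not None:
            unc = None
            if self.ref.use_uncertainty_input:
                _, unc = uncertainty_from_masks(main, aux1 if aux1 is not None
                                                else main,
                                                aux2 if aux2 is not None
                                                else main)
            _, refined = self.ref.refine(main, unc)
        return losses.total_loss(gt, main, aux1, aux2, refined)

    def predict_slice(self, image: np.ndarray, slice_seed: int,
                      refine: bool = True):
        """Segment one working-size slice (eval mode, no gradients).

        Returns ``(labels, uncertainty)`` in the working grid; uncertainty
        is ``None`` when no auxiliary decoder exists.
        """
        need_unc = self.seg.dec_aux1 is not None \
            or self.seg.dec_aux2 is not None
        with nn.no_grad():
            x = nn.Tensor(image[None, None].astype(nn.DTYPE))
            main, aux1, aux2 = self.seg.segment(x, perturb=need_unc,
                                                seed=slice_seed)
            unc_arr = None
            unc = None
            if need_unc:
                _, unc = uncertainty_from_masks(
                    main, aux1 if aux1 is not None else main,
                    aux2 if aux2 is not None else main)
                unc_arr = unc.data[0] if isinstance(unc, nn.Tensor) \
                    else np.asarray(unc)[0]
            if refine and self.ref is not None:
                if self.ref.use_uncertainty_input and unc is None:
                    raise ConfigError("refinement requires an uncertainty "
                                      "map but no auxiliary decoder exists")
                _, refined = self.ref.refine(
                    main, unc if self.ref.use_uncertainty_input else None)
                labels = refined_to_labels(refined.data[0])
            else:
                labels = binarize(main.data[0]).argmax(axis=0).astype(np.int64)
        return labels, unc_arr


@dataclass
class Checkpoint:
    """Model weights plus every configuration needed to reuse them."""

    net_cfg: NetConfig
    train_cfg: TrainConfig
    seg_state: dict
    ref_state: dict | None
    window: WindowSpec = field(default_factory=WindowSpec)
    work_size: tuple[int, int] = (64, 64)

    def build_model(self) -> Model:
        model = Model(self.net_cfg, self.train_cfg)
        model.seg.load_state_dict(self.seg_state)
        if self.ref_state is not None:
            if model.ref is None:
                raise ConfigError("checkpoint has refinement weights but "
                                  "use_refinement is off")
            model.ref.load_state_dict(self.ref_state)
        model.eval()
        return model

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {f"seg.{k}": v for k, v in self.seg_state.items()}
        if self.ref_state is not None:
            payload.update({f"ref.{k}": v for k, v in self.ref_state.items()})
        meta = json.dumps({
            "net_cfg": self.net_cfg.to_dict(),
            "train_cfg": self.train_cfg.to_dict(),
            "window": {"level": self.window.level, "width": self.window.width},
            "work_size": list(self.work_size),
            "has_refinement": self.ref_state is not None,
        })
        buf = io.BytesIO()
        np.savez(buf, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **payload)
        path.write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            seg_state = {k[4:]: data[k] for k in data.files
                         if k.startswith("seg.")}
            ref_state = {k[4:]: data[k] for k in data.files
                         if k.startswith("ref.")}
        return cls(
            net_cfg=NetConfig(**meta["net_cfg"]),
            train_cfg=TrainConfig(**meta["train_cfg"]),
            seg_state=seg_state,
            ref_state=ref_state if meta["has_refinement"] else None,
            window=WindowSpec(**meta["window"]),
            work_size=tuple(meta["work_size"]),
        )


def _batches(samples: list[SliceSample], batch_size: int,
             order: np.ndarray):
    for start in range(0, len(order), batch_size):
        chunk = [samples[i] for i in order[start:start + batch_size]]
        images = np.stack([s.image for s in chunk])[:, None].astype(nn.DTYPE)
        gts = np.stack([s.labels for s in chunk])
        yield images, gts


def train(samples: list[SliceSample], net_cfg: NetConfig,
          train_cfg: TrainConfig,
          window: WindowSpec = WindowSpec(),
          work_size: tuple[int, int] = (64, 64),
          ) -> tuple[Checkpoint, TrainHistory]:
    """Optimise the model on preprocessed slice samples.

    One Adam step per batch on the total deep-supervision loss.  Returns
    the trained checkpoint and the per-epoch loss history.
    """
    if not samples:
        raise ValueError("empty training set")
    from .preprocess import augment as _augment

    model = Model(net_cfg, train_cfg)
    model.train()
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)
    history = TrainHistory()
    rng = np.random.default_rng(train_cfg.seed)
    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(samples))
        totals: list[float] = []
        term_sums: dict[str, float] = {}
        n_steps = 0
        epoch_samples = samples
        if train_cfg.augment:
            epoch_samples = [
                _augment(s, seed=train_cfg.seed * 1_000_003 + epoch * 10_007
                         + i) for i, s in enumerate(samples)]
        for images, gts in _batches(epoch_samples, train_cfg.batch_size,
                                    order):
            loss = model.forward_loss(images, gts,
                                      step_seed=train_cfg.seed + 2 * step)
            opt.zero_grad()
            loss.total.backward()
            opt.step()
            totals.append(loss.value)
            for k, v in loss.breakdown().items():
                term_sums[k] = term_sums.get(k, 0.0) + v
            step += 1
            n_steps += 1
        history.epoch_loss.append(float(np.mean(totals)))
        history.epoch_terms.append(
            {k: v / n_steps for k, v in term_sums.items()})
        history.steps_per_epoch.append(n_steps)
    checkpoint = Checkpoint(
        net_cfg=net_cfg, train_cfg=train_cfg,
        seg_state=model.seg.state_dict(),
        ref_state=model.ref.state_dict() if model.ref is not None else None,
        window=window, work_size=tuple(work_size))
    return checkpoint, history


def predict(checkpoint: Checkpoint | Model, volume: np.ndarray,
            refine: bool = True, return_uncertainty: bool = False):
    """Segment a raw (slices, H, W) volume with a trained checkpoint.

    Each slice is windowed, body-cropped, resized, segmented, uncertainty-
    weighted, refined and mapped back to the original slice geometry; the
    per-slice label masks are stacked in acquisition order.  With
    ``return_uncertainty`` the per-class uncertainty is summed over classes
    and returned as a second 3-D map.
    """
    if isinstance(checkpoint, Model):
        model = checkpoint
        window, work_size = WindowSpec(), volume.shape[1:]
        seed = model.train_cfg.seed
    else:
        model = checkpoint.build_model()
        window, work_size = checkpoint.window, checkpoint.work_size
        seed = checkpoint.train_cfg.seed
    model.eval()
    samples = preprocess_volume(volume, None, window=window,
                                work_size=tuple(work_size))
    label_slices = []
    unc_slices = []
    for s, sample in enumerate(samples):
        labels, unc = model.predict_slice(
            sample.image, slice_seed=seed + 7919 * (s + 1), refine=refine)
        label_slices.append(postprocess_labels(labels, sample.box))
        if return_uncertainty:
            unc_total = unc.sum(axis=0) if unc is not None \
                else np.zeros_like(sample.image)
            unc_slices.append(postprocess_map(unc_total, sample.box))
    labels3d = metrics.stack_slices(label_slices)
    if return_uncertainty:
        return labels3d, metrics.stack_slices(unc_slices)
    return labels3d


def samples_from_volumes(volumes, window: WindowSpec = WindowSpec(),
                         work_size: tuple[int, int] = (64, 64)
                         ) -> list[SliceSample]:
    """Preprocess a list of phantom/real volumes into slice samples."""
    samples: list[SliceSample] = []
    for vid, vol in enumerate(volumes):
        samples.extend(preprocess_volume(vol.image, vol.labels,
                                         window=window, work_size=work_size,
                                         volume_id=vid))
    return samples


def run_ablation(grid: list[dict], train_volumes, test_volumes,
                 net_cfg: NetConfig, train_cfg: TrainConfig,
                 window: WindowSpec = WindowSpec(),
                 work_size: tuple[int, int] = (64, 64)) -> list[dict]:
    """Train and evaluate one model per flag configuration.

    ``grid`` entries are dicts of TrainConfig/NetConfig overrides, e.g.
    ``{"use_refinement": False}`` or ``{"noise_kind": "gaussian"}``.
    Each output row carries the configuration plus per-organ dice/HD.
    """
    samples = samples_from_volumes(train_volumes, window, work_size)
    organ_ids = sorted(int(c) for c in np.unique(
        np.concatenate([v.labels.ravel() for v in test_volumes])) if c > 0)
    rows = []
    for overrides in grid:
        net_over = {k: v for k, v in overrides.items()
                    if k in NetConfig.__dataclass_fields__}
        train_over = {k: v for k, v in overrides.items()
                      if k in TrainConfig.__dataclass_fields__}
        unknown = set(overrides) - set(net_over) - set(train_over)
        if unknown:
            raise ConfigError(f"unknown ablation keys: {sorted(unknown)}")
        cfg_n = NetConfig(**{**net_cfg.to_dict(), **net_over})
        cfg_t = TrainConfig(**{**train_cfg.to_dict(), **train_over})
        ckpt, _ = train(samples, cfg_n, cfg_t, window=window,
                        work_size=work_size)
        preds = [predict(ckpt, v.image) for v in test_volumes]
        gts = [v.labels for v in test_volumes]
        scores = metrics.score_patients(preds, gts, organ_ids)
        row = dict(overrides)
        for s in scores:
            row[f"dice_{s.organ}"] = s.dice
            row[f"dice_var_{s.organ}"] = s.dice_variance
            row[f"hd_{s.organ}"] = s.hd
            row[f"hd_var_{s.organ}"] = s.hd_variance
        rows.append(row)
    return rows
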