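"""Training harness: loss registry, Adam optimizer, training loop, evaluation.

Every loss in the package is registered under a short name so the
harness (and CLI) can train the tiny U-Net with any of them:

====== =====================================================
name    loss
====== =====================================================
bce     binary cross-entropy
dice    soft dice
hybrid  static α·dice + β·BCE
focal   focal loss with a fixed focusing parameter
qr_asp  R-ASP, median (quantile) grouping
vr_asp  R-ASP, mean (value) grouping
cr_asp  R-ASP, exact 2-means (cluster) grouping
lr_asp  learned per-sample dice/BCE weights
d_asp   density-driven hybrid with region-level term
sr_asp  focal with υ selected by size group
sd_asp  focal with υ selected by density category
====== =====================================================

ASP losses are computed per sample — each sample's own p_i, density
category or learned weights — and averaged over the mini-batch, so the
batch loss is invariant to permuting samples within the batch.  The
grouping model must be fitted on the training split only, before
training, and is frozen; the harness refuses to start if a loss needs a
grouping model (or compatible metadata) that is missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .asp import (
    AdaptiveFocalConfig,
    GroupingModel,
    LraspWeightNet,
    SampleMeta,
    adaptive_focal_loss,
    assign_group,
    dasp_loss,
    fit_grouping,
    lrasp_loss,
    rasp_loss,
)
from .autodiff import Tensor
from .config import LossConfig
from .exceptions import ConfigError, DataError
from .metrics import MetricReport, evaluate_dataset
from .model import UNet, build_model
from .pixel_losses import bce_loss, dice_loss, focal_loss, hybrid_pixel_loss

__all__ = ["LOSS_NAMES", "TrainConfig", "TrainRecord", "Adam",
           "make_loss", "train", "evaluate", "kfold_split"]

#: loss name -> (needs grouping model, grouping strategy constraint)
_LOSS_TABLE = {
    "bce": (False, None),
    "dice": (False, None),
    "hybrid": (False, None),
    "focal": (False, None),
    "qr_asp": (True, "quantile"),
    "vr_asp": (True, "value"),
    "cr_asp": (True, "cluster"),
    "lr_asp": (False, None),
    "d_asp": (False, None),
    "sr_asp": (True, None),
    "sd_asp": (False, None),
}
LOSS_NAMES = tuple(_LOSS_TABLE)


def make_loss(name: str, cfg: LossConfig, grouping: GroupingModel | None = None,
              weight_net: LraspWeightNet | None = None):
    """Build ``loss(pred2d, gt2d, meta) -> Tensor`` for a registered name."""
    if name not in _LOSS_TABLE:
        raise ConfigError(f"unknown loss {name!r}; registered: {sorted(_LOSS_TABLE)}")
    needs_grouping, strategy = _LOSS_TABLE[name]
    if needs_grouping:
        if grouping is None:
            raise DataError(f"loss {name!r} requires a fitted grouping model")
        if strategy is not None and grouping.strategy != strategy:
            raise ConfigError(
                f"loss {name!r} expects a {strategy!r} grouping model, "
                f"got {grouping.strategy!r}")
    cfg.validate()
    px = cfg.pixel

    if name == "bce":
        return lambda pred, gt, meta: bce_loss(pred, gt, px.prob_clamp)
    if name == "dice":
        return lambda pred, gt, meta: dice_loss(pred, gt, px.dice_epsilon,
                                                px.dice_dialect)
    if name == "hybrid":
        return lambda pred, gt, meta: hybrid_pixel_loss(pred, gt, px)
    if name == "focal":
        ups = cfg.focal.upsilon_fixed
        return lambda pred, gt, meta: focal_loss(pred, gt, ups, cfg.focal.prob_clamp)
    if name in ("qr_asp", "vr_asp", "cr_asp"):
        def rasp(pred, gt, meta, _g=grouping):
            p = assign_group(_g, meta.ratio)
            return rasp_loss(pred, gt, p, cfg.rasp, px)
        return rasp
    if name == "lr_asp":
        if weight_net is None:
            raise DataError("loss 'lr_asp' requires an LraspWeightNet")
        return lambda pred, gt, meta: lrasp_loss(pred, gt, weight_net, px)
    if name == "d_asp":
        return lambda pred, gt, meta: dasp_loss(pred, gt, meta.density_category,
                                                cfg.dasp)
    if name == "sr_asp":
        fcfg = AdaptiveFocalConfig(mode="ratio",
                                   upsilon_by_group=cfg.focal.upsilon_by_group,
                                   prob_clamp=cfg.focal.prob_clamp)

        def sr(pred, gt, meta, _g=grouping):
            m = SampleMeta(meta.ratio, meta.density_category,
                           group=assign_group(_g, meta.ratio))
            return adaptive_focal_loss(pred, gt, m, fcfg)
        return sr
    # sd_asp
    fcfg = AdaptiveFocalConfig(mode="density",
                               upsilon_by_density=cfg.focal.upsilon_by_density,
                               prob_clamp=cfg.focal.prob_clamp)
    return lambda pred, gt, meta: adaptive_focal_loss(pred, gt, meta, fcfg)


class Adam:
    """Adam optimizer over a list of autodiff tensors."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainConfig:
    loss_name: str = "hybrid"
    epochs: int = 5
    batch_size: int = 4
    learning_rate: float = 1e-4
    image_size: tuple = (64, 64)
    seed: int = 0
    model_descriptor: str = "unet3-16"
    val_fraction: float = 0.1
    threshold: float = 0.5
    loss_config: LossConfig = field(default_factory=LossConfig)

    def validate(self) -> "TrainConfig":
        if self.loss_name not in _LOSS_TABLE:
            raise ConfigError(f"unknown loss {self.loss_name!r}")
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ConfigError("val_fraction must lie in [0, 1)")
        self.loss_config.validate()
        return self


@dataclass
class TrainRecord:
    """Append-only per-epoch history plus the config snapshot."""

    loss_name: str
    seed: int
    epochs: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def log(self, **kwargs):
        self.epochs.append(kwargs)

    @property
    def train_losses(self):
        return [e["train_loss"] for e in self.epochs]

    def to_json(self) -> str:
        return json.dumps({"loss_name": self.loss_name, "seed": self.seed,
                           "epochs": self.epochs, "config": self.config},
                          indent=2)


def _check_dataset(dataset, cfg: TrainConfig):
    if len(dataset) == 0:
        raise DataError("cannot train on an empty dataset")
    for s in dataset:
        meta = s.meta
        if meta is None:
            raise DataError("every sample needs SampleMeta for ASP losses")
        meta.validate()


def train(dataset, cfg: TrainConfig, grouping: GroupingModel | None = None,
          weight_net: LraspWeightNet | None = None):
    """Train the tiny U-Net on (image, mask, meta) samples.

    Returns ``(record, model)``.  ASP losses receive each sample's own
    metadata; the batch loss is the mean of the per-sample losses.  When
    a validation split is held out, the parameters with the best
    validation DSC are restored at the end.
    """
    cfg.validate()
    _check_dataset(dataset, cfg)
    if cfg.loss_name == "lr_asp" and weight_net is None:
        weight_net = LraspWeightNet(image_size=cfg.image_size, seed=cfg.seed)
    loss_fn = make_loss(cfg.loss_name, cfg.loss_config, grouping, weight_net)

    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(dataset))
    n_val = int(round(cfg.val_fraction * len(dataset)))
    val_idx, train_idx = idx[:n_val], idx[n_val:]
    if len(train_idx) == 0:
        raise DataError("validation split leaves no training samples")

    model = build_model(cfg.model_descriptor, seed=cfg.seed)
    params = model.parameters
    if cfg.loss_name == "lr_asp":
        params = params + weight_net.parameters
    opt = Adam(params, lr=cfg.learning_rate)

    record = TrainRecord(loss_name=cfg.loss_name, seed=cfg.seed,
                         config={"epochs": cfg.epochs, "batch_size": cfg.batch_size,
                                 "learning_rate": cfg.learning_rate,
                                 "model": cfg.model_descriptor,
                                 "val_fraction": cfg.val_fraction})
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [dataset[i] for i in order[start:start + cfg.batch_size]]
            images = np.stack([s.image for s in batch]).astype(np.float32)
            preds = model.forward(images)
            loss = batch_loss(preds, batch, loss_fn)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if len(val_idx) > 0:
            rep = evaluate(model, [dataset[i] for i in val_idx], cfg.threshold)
            entry["val_dsc"] = rep.dsc
            if rep.dsc > best[0]:
                best = (rep.dsc, model.state_dict())
        record.log(**entry)
    if best[1] is not None:
        model.load_state_dict(best[1])
    return record, model


def batch_loss(preds: Tensor, batch, loss_fn) -> Tensor:
    """Mean of per-sample losses; each sample keeps its own metadata."""
    total = None
    for i, s in enumerate(batch):
        li = loss_fn(preds[i, 0], s.mask, s.meta)
        total = li if total is None else total + li
    return total * (1.0 / len(batch))


def evaluate(model: UNet, dataset, threshold: float = 0.5,
             batch_size: int = 8) -> MetricReport:
    """Run inference and score with the package metrics."""
    if len(dataset) == 0:
        raise DataError("cannot evaluate an empty dataset")
    preds = []
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start:start + batch_size]
        images = np.stack([s.image for s in chunk]).astype(np.float32)
        preds.extend(list(model.predict(images)))
    gts = [s.mask for s in dataset]
    ids = [getattr(s.meta, "sample_id", None) or i for i, s in enumerate(dataset)]
    return evaluate_dataset(preds, gts, threshold=threshold, sample_ids=ids)


def fit_grouping_for(dataset, strategy: str = "cluster", k: int = 2,
                     seed: int = 0) -> GroupingModel:
    """Fit a grouping model from the mass ratios of a (training) dataset."""
    return fit_grouping([s.meta.ratio for s in dataset], strategy, k=k, seed=seed)


def kfold_split(n: int, k: int = 5, seed: int = 0):
    """Deterministic k-fold cross-validation index splits."""
    if k < 2 or k > n:
        raise DataError(f"need 2 <= k <= n, got k={k}, n={n}")
    idx = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(idx, k)
    return [(np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
            for i in range(k)]
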