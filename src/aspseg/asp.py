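"""Adaptive sample-level prioritizing (ASP) losses.

Whole-view mammograms suffer from severe, *variable* pixel class
imbalance: a mass can occupy anywhere from under 1% to about a third of
the image, and denser breast tissue (higher ACR category) makes the mass
harder to separate from its background.  Classic hybrid losses use fixed
term weights for every sample.  The ASP family instead re-weights the
terms of a hybrid loss per sample, using metadata that is free at
training time:

* **R-ASP** (ratio-driven): the mass-to-image ratio r_i assigns each
  sample to a small or large group (p_i ∈ {0, 1}); the dice term is
  prioritized for small masses (severe imbalance) and the BCE term for
  large ones:

      L_R-ASP = (I_dice + (1−p)^γ_d)·L_dice + (I_bce + p^γ_b)·L_bce

  Grouping strategies: median split (quantile), mean split (value), or
  exact 1-D 2-means clustering (cluster) — the latter suits the
  right-skewed ratio distributions seen in practice.

* **LR-ASP** (learned): a small trainable module maps the ground-truth
  mask to the two term weights, trained jointly with the segmentation
  network.

* **D-ASP** (density-driven): a prioritizing vector θ (one weight per
  ACR density category) scales a region-level loss term added to the
  pixel-level hybrid:  L_D-ASP = (d_i·θ)·L_HR + L_HP, where d_i is the
  one-hot density encoding — denser tissue gets more regional context.

* **SR-/SD-ASP** (single-loss): focal loss whose focusing parameter υ is
  selected per sample from its ratio group or density category, so easy
  pixels in easy samples are down-weighted hardest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, as_tensor, avg_pool2d
from .exceptions import ConfigError, DataError, DomainError, StateError
from .masks import validate_bin_mask
from .pixel_losses import PixelLossConfig, bce_loss, dice_loss, focal_loss, hybrid_pixel_loss
from .region_losses import RegionLossConfig, hybrid_region_loss

__all__ = [
    "SampleMeta", "GroupingModel", "RaspConfig", "DaspConfig",
    "AdaptiveFocalConfig", "LraspWeightNet",
    "mass_ratio", "fit_grouping", "assign_group",
    "rasp_loss", "lrasp_weights", "lrasp_loss",
    "dasp_region_coefficient", "dasp_loss",
    "adaptive_upsilon", "adaptive_focal_loss",
]

SMALL, LARGE = 0, 1


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

@dataclass
class SampleMeta:
    """Per-sample metadata: mass ratio, ACR density category, size group."""

    ratio: float
    density_category: int = 1
    group: int | None = None     # 0 = small, 1 = large, None = unassigned
    sample_id: str | None = None

    def validate(self) -> "SampleMeta":
        if not (0.0 <= self.ratio <= 1.0):
            raise DomainError(f"ratio must lie in [0, 1], got {self.ratio}")
        if self.density_category not in (1, 2, 3, 4):
            raise DomainError(
                f"density_category must be an ACR class 1-4, got {self.density_category}")
        if self.group not in (None, SMALL, LARGE):
            raise DomainError(f"group must be 0, 1 or None, got {self.group}")
        return self


def mass_ratio(gt) -> float:
    """Fraction of mask pixels that are positive (mass area / image area)."""
    arr = validate_bin_mask(gt)
    return float(arr.sum()) / arr.size


# ---------------------------------------------------------------------------
# grouping models
# ---------------------------------------------------------------------------

def _exact_kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means centres by dynamic programming over sorted values.

    Optimal clusters of sorted 1-D data are contiguous runs, so the
    optimum is found exactly by DP on split points; no iterative
    refinement or seed sensitivity is involved.
    """
    x = np.sort(values)
    n = len(x)
    k = min(k, n)
    c = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def seg_cost(i, j):  # cost of cluster x[i:j]
        s, s2, m = c[j] - c[i], c2[j] - c2[i], j - i
        return s2 - s * s / m

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            for i in range(kk - 1, j):
                cand = cost[kk - 1, i] + seg_cost(i, j)
                if cand < cost[kk, j]:
                    cost[kk, j] = cand
                    back[kk, j] = i
    bounds = [n]
    j = n
    for kk in range(k, 0, -1):
        j = back[kk, j]
        bounds.append(j)
    bounds = bounds[::-1]
    centers = np.array([x[bounds[i]:bounds[i + 1]].mean() for i in range(k)])
    return np.sort(centers)


@dataclass
class GroupingModel:
    """Fitted small/large divider over training mass ratios."""

    strategy: str                       # "quantile", "value" or "cluster"
    threshold: float | None = None      # median/mean of training ratios
    centers: tuple | None = None        # ascending cluster centres
    fitted_on: int = 0

    def validate(self) -> "GroupingModel":
        if self.strategy not in ("quantile", "value", "cluster"):
            raise ConfigError(f"unknown grouping strategy {self.strategy!r}")
        if self.strategy == "cluster":
            if not self.centers or len(self.centers) < 2:
                raise ConfigError("cluster strategy requires at least two centres")
            if any(b <= a for a, b in zip(self.centers, self.centers[1:])):
                raise ConfigError("cluster centres must be strictly increasing")
            if self.threshold is not None:
                raise ConfigError("cluster strategy does not use a threshold")
        else:
            if self.threshold is None:
                raise ConfigError(f"{self.strategy} strategy requires a threshold")
            if self.centers is not None:
                raise ConfigError(f"{self.strategy} strategy does not use centres")
        return self

    def to_json(self) -> str:
        d = asdict(self)
        if d["centers"] is not None:
            d["centers"] = list(d["centers"])
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroupingModel":
        d = json.loads(text)
        if d.get("centers") is not None:
            d["centers"] = tuple(d["centers"])
        return cls(**d).validate()


def fit_grouping(ratios, strategy: str = "cluster", k: int = 2,
                 seed: int = 0) -> GroupingModel:
    """Fit a small/large grouping model on training mass ratios.

    quantile → median split; value → mean split; cluster → exact 1-D
    k-means (k=2 by default; the seed is accepted for API symmetry but
    the solver is deterministic).
    """
    ratios = np.asarray(list(ratios), dtype=float)
    if ratios.size == 0:
        raise DataError("cannot fit a grouping model on an empty ratio list")
    if ratios.min() < 0 or ratios.max() > 1:
        raise DomainError("ratios must lie in [0, 1]")
    if strategy == "quantile":
        model = GroupingModel("quantile", threshold=float(np.median(ratios)),
                              fitted_on=ratios.size)
    elif strategy == "value":
        model = GroupingModel("value", threshold=float(np.mean(ratios)),
                              fitted_on=ratios.size)
    elif strategy == "cluster":
        if k < 2:
            raise ConfigError("cluster strategy requires k >= 2")
        centers = _exact_kmeans_1d(ratios, k)
        model = GroupingModel("cluster", centers=tuple(float(c) for c in centers),
                              fitted_on=ratios.size)
    else:
        raise ConfigError(f"unknown grouping strategy {strategy!r}")
    return model.validate()


def assign_group(model: GroupingModel, ratio: float) -> int:
    """Map a mass ratio to the small (0) or large (1) group.

    Threshold strategies put a ratio exactly at the threshold into the
    small group; the cluster strategy assigns to the nearest centre with
    ties toward the smallest centre, and a sample is "large" iff its
    nearest centre is not the smallest one.
    """
    if not isinstance(model, GroupingModel):
        raise StateError("assign_group requires a fitted GroupingModel")
    model.validate()
    if not (0.0 <= ratio <= 1.0):
        raise DomainError(f"ratio must lie in [0, 1], got {ratio}")
    if model.strategy in ("quantile", "value"):
        return SMALL if ratio <= model.threshold else LARGE
    centers = np.asarray(model.centers)
    nearest = int(np.argmin(np.abs(centers - ratio)))  # argmin breaks ties low
    return SMALL if nearest == 0 else LARGE


def assign_groups(model: GroupingModel, metas) -> None:
    """Assign ``meta.group`` in place for a collection of SampleMeta."""
    for m in metas:
        m.group = assign_group(model, m.ratio)


def write_metadata_csv(path, metas) -> None:
    """Write sample metadata as CSV (sample_id, ratio, density_category, group)."""
    import pandas as pd

    rows = [{"sample_id": m.sample_id, "ratio": m.ratio,
             "density_category": m.density_category,
             "group": "" if m.group is None else m.group}
            for m in metas]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_metadata_csv(path) -> list:
    """Read sample metadata written by :func:`write_metadata_csv`."""
    import pandas as pd

    df = pd.read_csv(path)
    metas = []
    for row in df.itertuples():
        group = getattr(row, "group", None)
        group = None if group is None or pd.isna(group) else int(group)
        metas.append(SampleMeta(ratio=float(row.ratio),
                                density_category=int(row.density_category),
                                group=group,
                                sample_id=str(row.sample_id)).validate())
    return metas


# ---------------------------------------------------------------------------
# R-ASP
# ---------------------------------------------------------------------------

@dataclass
class RaspConfig:
    """R-ASP hyperparameters (initial weights and ratio exponents)."""

    i_dice: float = 1.0
    i_bce: float = 1.0
    gamma_dice: float = 0.25
    gamma_bce: float = 0.35
    p_mode: str = "binary"       # "binary" (grouped) or "continuous"

    def validate(self) -> "RaspConfig":
        if self.i_dice < 0 or self.i_bce < 0:
            raise ConfigError("initial weights must be non-negative")
        if self.gamma_dice <= 0 or self.gamma_bce <= 0:
            raise ConfigError("gamma exponents must be positive")
        if self.p_mode not in ("binary", "continuous"):
            raise ConfigError(f"unknown p_mode {self.p_mode!r}")
        return self


def rasp_weights(p: float, cfg: RaspConfig) -> tuple:
    """The (dice, BCE) coefficients of R-ASP for prioritization signal p."""
    cfg.validate()
    if cfg.p_mode == "binary":
        if p not in (0, 1):
            raise DomainError(f"binary p_mode requires p in {{0, 1}}, got {p}")
    elif not (0.0 <= p <= 1.0):
        raise DomainError(f"continuous p_mode requires p in [0, 1], got {p}")
    w_dice = cfg.i_dice + (1.0 - p) ** cfg.gamma_dice
    w_bce = cfg.i_bce + p ** cfg.gamma_bce
    return float(w_dice), float(w_bce)


def rasp_loss(pred, gt, p, cfg: RaspConfig | None = None,
              pixel_cfg: PixelLossConfig | None = None):
    """Ratio-driven ASP loss: per-sample re-weighted dice + BCE hybrid.

    Small-group samples (p=0) get the dice term prioritized, large-group
    samples (p=1) the BCE term.
    """
    cfg = (cfg or RaspConfig()).validate()
    pixel_cfg = (pixel_cfg or PixelLossConfig()).validate()
    w_dice, w_bce = rasp_weights(p, cfg)
    d = dice_loss(pred, gt, pixel_cfg.dice_epsilon, pixel_cfg.dice_dialect)
    b = bce_loss(pred, gt, pixel_cfg.prob_clamp)
    return w_dice * d + w_bce * b


# ---------------------------------------------------------------------------
# LR-ASP
# ---------------------------------------------------------------------------

class LraspWeightNet:
    """Small trainable map from a ground-truth mask to two loss weights.

    Architecture: ``pool``× average pooling of the mask, flatten, two
    dense layers (tanh-free, ReLU hidden), two outputs.  Under the
    default sum normalization the outputs pass through a softmax scaled
    by 2, so they are strictly positive and sum to 2 (the static hybrid
    with unit weights is the symmetric point); the unnormalized mode
    applies softplus instead.
    """

    def __init__(self, image_size=(64, 64), pool: int = 4, hidden: int = 16,
                 normalization: str = "sum", seed: int = 0):
        if normalization not in ("sum", "none"):
            raise ConfigError(f"unknown normalization {normalization!r}")
        H, W = image_size
        if H % pool or W % pool:
            raise ConfigError(f"image size {image_size} not divisible by pool {pool}")
        self.image_size = (H, W)
        self.pool = pool
        self.hidden = hidden
        self.normalization = normalization
        n_in = (H // pool) * (W // pool)
        rng = np.random.default_rng(seed)
        s1 = np.sqrt(2.0 / n_in)
        self.w1 = Tensor(rng.normal(0.0, s1, (n_in, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, 2)),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(2), requires_grad=True)

    @property
    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2]

    def describe(self) -> dict:
        return {"image_size": list(self.image_size), "pool": self.pool,
                "hidden": self.hidden, "normalization": self.normalization}

    def forward(self, gt) -> Tensor:
        arr = validate_bin_mask(gt)
        if arr.shape != self.image_size:
            raise ConfigError(
                f"weight net built for {self.image_size}, got mask {arr.shape}")
        x = avg_pool2d(as_tensor(arr), self.pool).reshape(1, -1)
        h = (x @ self.w1 + self.b1.reshape(1, -1)).relu()
        z = (h @ self.w2 + self.b2.reshape(1, -1)).reshape(2)
        if self.normalization == "sum":
            e = (z - float(z.data.max())).exp()   # stabilized softmax
            return e * 2.0 / e.sum()
        # softplus keeps unnormalized weights strictly positive
        return (1.0 + z.exp()).log()


def lrasp_weights(gt, net: LraspWeightNet):
    """Evaluate the weight net: returns (w_dice, w_bce) as floats."""
    out = net.forward(gt)
    return float(out.data[0]), float(out.data[1])


def lrasp_loss(pred, gt, net: LraspWeightNet,
               pixel_cfg: PixelLossConfig | None = None):
    """Learning-based R-ASP: learned per-sample weights on dice and BCE.

    Gradients flow both to the prediction and to the weight-net
    parameters (the ground truth itself is not differentiated).
    """
    pixel_cfg = (pixel_cfg or PixelLossConfig()).validate()
    w = net.forward(gt)
    d = dice_loss(pred, gt, pixel_cfg.dice_epsilon, pixel_cfg.dice_dialect)
    b = bce_loss(pred, gt, pixel_cfg.prob_clamp)
    loss = w[0] * as_tensor(d) + w[1] * as_tensor(b)
    # plain-array predictions get a plain float back (the weight-net graph
    # is only kept alive when the caller is differentiating)
    return loss if isinstance(pred, Tensor) else loss.item()


# ---------------------------------------------------------------------------
# D-ASP
# ---------------------------------------------------------------------------

@dataclass
class DaspConfig:
    """D-ASP hyperparameters: density prioritizing vector and sub-losses."""

    theta: tuple = (0.5, 0.5, 0.85, 0.95)
    pixel: PixelLossConfig = field(default_factory=PixelLossConfig)
    region: RegionLossConfig = field(default_factory=RegionLossConfig)

    def validate(self) -> "DaspConfig":
        if len(self.theta) != 4 or any(t < 0 for t in self.theta):
            raise ConfigError("theta must be a 4-vector of non-negative weights")
        self.pixel.validate()
        self.region.validate()
        return self


def dasp_region_coefficient(density_category: int, theta) -> float:
    """One-hot density encoding dotted with the prioritizing vector θ.

    ACR categories are 1-indexed: category c selects θ[c−1].
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (4,) or (theta < 0).any():
        raise ConfigError("theta must be a 4-vector of non-negative weights")
    if density_category not in (1, 2, 3, 4):
        raise DomainError(
            f"density_category must be in 1..4, got {density_category}")
    onehot = np.zeros(4)
    onehot[density_category - 1] = 1.0
    return float(onehot @ theta)


def dasp_loss(pred, gt, density_category: int, cfg: DaspConfig | None = None):
    """Density-driven ASP loss: (d·θ)·L_HR + L_HP.

    The region-level hybrid (RMI + SSIM) is scaled up for denser
    categories, where neighbourhood context matters most; the pixel-level
    hybrid is always present.
    """
    cfg = (cfg or DaspConfig()).validate()
    coef = dasp_region_coefficient(density_category, cfg.theta)
    hp = hybrid_pixel_loss(pred, gt, cfg.pixel)
    if coef == 0.0:
        return hp
    hr = hybrid_region_loss(pred, gt, cfg.region)
    return coef * hr + hp


# ---------------------------------------------------------------------------
# adaptive focal (SR-ASP / SD-ASP)
# ---------------------------------------------------------------------------

@dataclass
class AdaptiveFocalConfig:
    """Per-sample selection table for the focal focusing parameter υ."""

    mode: str = "ratio"                               # "ratio" or "density"
    upsilon_by_group: tuple = (0.25, 0.5)             # (small, large)
    upsilon_by_density: tuple = (0.2, 0.25, 0.3, 0.35)
    upsilon_fixed: float = 0.5        # plain (non-adaptive) focal fallback
    prob_clamp: float = 1e-7

    def validate(self) -> "AdaptiveFocalConfig":
        if self.mode not in ("ratio", "density"):
            raise ConfigError(f"unknown adaptive focal mode {self.mode!r}")
        if self.upsilon_fixed < 0:
            raise ConfigError("upsilon_fixed must be non-negative")
        if len(self.upsilon_by_group) != 2 or any(u < 0 for u in self.upsilon_by_group):
            raise ConfigError("upsilon_by_group must be two non-negative values")
        if len(self.upsilon_by_density) != 4 or any(u < 0 for u in self.upsilon_by_density):
            raise ConfigError("upsilon_by_density must be four non-negative values")
        return self


def adaptive_upsilon(meta: SampleMeta, cfg: AdaptiveFocalConfig | None = None) -> float:
    """Select the focal focusing parameter from the sample's metadata."""
    cfg = (cfg or AdaptiveFocalConfig()).validate()
    meta.validate()
    if cfg.mode == "ratio":
        if meta.group is None:
            raise StateError(
                "ratio-mode adaptive focal loss requires an assigned size group")
        return float(cfg.upsilon_by_group[meta.group])
    return float(cfg.upsilon_by_density[meta.density_category - 1])


def adaptive_focal_loss(pred, gt, meta: SampleMeta,
                        cfg: AdaptiveFocalConfig | None = None):
    """Focal loss with a per-sample focusing parameter (SR-/SD-ASP)."""
    cfg = (cfg or AdaptiveFocalConfig()).validate()
    upsilon = adaptive_upsilon(meta, cfg)
    return focal_loss(pred, gt, upsilon, cfg.prob_clamp)
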