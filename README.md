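# aspseg

Adaptive sample-level prioritizing (ASP) losses for binary mass segmentation
in mammography-like images, with a synthetic phantom generator, evaluation
metrics, and a CPU-scale training harness.

## The problem

Whole-view mammogram mass segmentation fights two sample-dependent
difficulties. The mass-to-image ratio r_i spans under 1% to ~30%, so the
pixel class imbalance that plagues binary segmentation losses varies
drastically *across* samples; and the ACR breast-density category (1–4)
controls how well a mass separates from surrounding tissue. Conventional
hybrid losses (for example α·L_Dice + β·L_BCE) use one fixed weighting for
every sample. ASP losses instead set the weights per sample from metadata
that is free at training time:

- **R-ASP** (ratio-driven):
  `L_i = (I_Dice + (1−p_i)^γ)·L_Dice + (I_BCE + p_i^γ)·L_BCE`,
  where p_i ∈ {0,1} flags the large-mass group. The divider is a median
  split (QR-ASP), a mean split (VR-ASP), or exact 1-D 2-means clustering
  (CR-ASP); LR-ASP learns the two weights from the ground-truth mask with a
  small subnetwork trained jointly.
- **D-ASP** (density-driven): `L_i = (d_i·θ)·L_HR + L_HP`, where d_i is the
  one-hot density encoding, θ a per-category prioritizing vector, L_HP the
  pixel-level hybrid and L_HR = η·L_RMI + τ·L_SSIM a region-level hybrid of
  regional mutual information and structural-similarity losses.
- **SR-/SD-ASP**: focal loss `−(1−Ŷ_t)^υ log Ŷ_t` whose focusing parameter
  υ is selected per sample from its ratio group or density category.

Everything is differentiable end to end: the package ships a compact
reverse-mode autodiff core on NumPy arrays (convolutions, pooling, matrix
inverse/log-determinant) that powers both the losses and a tiny U-Net
harness, so no deep-learning framework is required.

It is written for researchers studying class-imbalance-aware loss design who
want a tested, dependency-light reference implementation of the ASP family
plus the infrastructure (synthetic data, metrics, training loop) to probe it.

## Worked example

```python
import numpy as np
from aspseg import (PhantomSpec, TrainConfig, fit_grouping, generate_dataset,
                    preset, rasp_loss, train, evaluate)
from aspseg.asp import assign_group

# 200 synthetic phantoms: right-skewed mass ratios, 4 density categories
phantoms = generate_dataset(PhantomSpec(seed=5), 200)
ratios = [s.meta.ratio for s in phantoms]

# cluster grouping (CR-ASP): exact 1-D 2-means over the training ratios
grouping = fit_grouping(ratios, "cluster", k=2)
print("cluster centres:", [round(c, 4) for c in grouping.centers])

# per-sample R-ASP loss for one small and one large mass
cfg = preset("inbreast")
s_small = min(phantoms, key=lambda s: s.meta.ratio)
p = assign_group(grouping, s_small.meta.ratio)
print("small mass ratio %.4f -> group %d" % (s_small.meta.ratio, p))

# train the tiny U-Net with the static hybrid loss, then evaluate
record, model = train(phantoms, TrainConfig(loss_name="hybrid", seed=13))
print("train loss per epoch:", [round(l, 3) for l in record.train_losses])
print("training-set DSC: %.3f" % evaluate(model, phantoms).dsc)
```

prints

```
cluster centres: [0.0264, 0.0922]
small mass ratio 0.0034 -> group 0
train loss per epoch: [1.121, 0.933, 0.815, 0.792, 0.771]
training-set DSC: 0.686
```

The cluster divider lands between the bulk of small masses (median ratio
≈ 3%) and the long right tail; the smallest mass falls in group 0, so its
dice term would be prioritized under R-ASP. Five epochs of Adam at the
reference learning rate 1e−4 steadily reduce the hybrid loss, and the
trained network reaches a mean dice similarity coefficient of 0.69 on the
training phantoms (an untrained network scores ≈ 0).

The same workflow is available from the shell:

```bash
aspseg synth --out data --n 200 --seed 5
aspseg fit-grouping --ratios data/metadata.csv --strategy cluster --out grouping.json
aspseg train --data data --loss cr_asp --preset inbreast --out run
aspseg evaluate --checkpoint run.npz --data data
```

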