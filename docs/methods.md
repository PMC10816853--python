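# Methods

## Problem setting

Binary mass segmentation in whole-view mammograms exhibits two sample-level
difficulty axes that ordinary segmentation losses ignore. First, the mass
occupies anywhere from under 1% to roughly a third of the image, so the
severity of pixel class imbalance varies strongly *between* samples, not just
within them. Second, the ACR breast-density category (1–4) controls how well
the mass separates from surrounding tissue: the denser the breast, the harder
the boundary. Adaptive sample-level prioritizing (ASP) losses inject exactly
this per-sample metadata into the weighting of a hybrid loss.

## The loss family

### Pixel-level terms

For a predicted probability mask ŷ and binary ground truth y over an H×W
grid:

- **BCE** — mean over pixels of −[y log ŷ + (1−y) log(1−ŷ)], with ŷ clamped
  into [ε_c, 1−ε_c], ε_c = 1e−7, before the logarithm. The mean (rather than
  the sum) makes magnitudes comparable across resolutions, so the α/β/I
  weights transfer between image sizes.
- **Soft dice** — a single global quotient, 1 − (Σŷy + ϵ)/(Σŷ + Σy + ϵ) with
  smoothing ϵ = 1 by default. Two dialects exist: the default keeps the plain
  intersection in the numerator; `dialect="standard"` uses the conventional
  2Σŷy, under which 1 − loss equals the dice similarity coefficient for hard
  masks as ϵ→0. Both are tested; the choice is a config switch because the
  two conventions circulate side by side in the literature.
- **Focal** — mean of −(1−Ŷ_t)^υ log Ŷ_t where Ŷ_t is the predicted
  probability of the *true* class. υ = 0 recovers BCE exactly; the loss is
  non-increasing in υ pointwise, which the adaptive variants exploit.

The static pixel hybrid is L_HP = α·dice + β·BCE.

### Region-level terms

- **SSIM loss** — mean over all valid sliding windows of 1 − SSIM, computed
  from windowed means, variances and covariance with C1 = (0.01 L)²,
  C2 = (0.03 L)², dynamic range L = 1, and an 11×11 Gaussian window with
  σ = 1.5 (the original SSIM convention). A uniform window mode exists so
  that a literal per-window loop oracle can reproduce the value exactly.
- **RMI loss** — the exact regional mutual information between neighbourhood
  "points" is intractable, so the loss uses the standard Gaussian lower
  bound. Each pixel's 3×3 neighbourhood (after average-pooling by 2) is a
  9-dimensional point; with mean-centred point matrices Y (truth) and P
  (prediction),

      MI ≥ (1/2d)·[log det(Σ_Y + εI) − log det(Σ_{Y|P} + εI)],
      Σ_{Y|P} = Σ_Y − Σ_YP (Σ_P + εI)⁻¹ Σ_PY,

  and the loss is −MI. Because Σ_{Y|P} ⪯ Σ_Y, the loss is ≤ 0 with its
  maximum (0) attained at statistical independence, and it decreases as the
  prediction becomes informative about ground-truth neighbourhoods. ε is
  5e−4 times the mean covariance diagonal plus an absolute floor of 1e−8, so
  constant (zero-variance) masks remain finite and score exactly 0.
  Covariance and determinant algebra runs in double precision to avoid
  cancellation on near-binary masks.

The static region hybrid is L_HR = η·RMI + τ·SSIM with η = τ = 1 defaults.

### Sample-level prioritizing

- **R-ASP**: L = (I_dice + (1−p)^γ_d)·dice + (I_bce + p^γ_b)·BCE, where
  p ∈ {0,1} marks the large-mass group. Small masses (p = 0) get the dice
  term prioritized — overlap-based losses stay informative under extreme
  imbalance — while large masses lean on BCE. Note that for binary p the
  exponents are inert (0^γ = 0, 1^γ = 1); a regression test documents this.
  A `continuous` mode (p = raw ratio) is provided where γ genuinely shapes
  the weighting; the binary mode is the default because grouping is what
  stabilizes training against ratio jitter.
- **Grouping strategies**: median split (`quantile`), mean split (`value`),
  or 1-D 2-means (`cluster`). The k-means solver is exact — dynamic
  programming over sorted ratios — because optimal 1-D clusters are
  contiguous; this removes Lloyd-iteration seed sensitivity entirely (the
  seed argument remains for API symmetry). Ratios exactly at a threshold go
  to the small group; cluster ties break toward the smaller centre. The
  grouping model is fitted on the training split only and then frozen.
- **LR-ASP**: a small trainable module (4× average-pooled ground-truth mask →
  dense(16) → dense(2)) outputs the two term weights, trained jointly with
  the segmentation network. Jointly minimizing a weighted loss over free
  positive weights collapses to zero, so the default normalization passes
  the two outputs through a softmax scaled by 2: strictly positive weights
  summing to 2, with (1,1) the symmetric point. An unnormalized softplus
  mode exists for experimentation.
- **D-ASP**: L = (d·θ)·L_HR + L_HP, where d is the one-hot ACR category and
  θ a 4-vector of prioritizing weights. Denser categories receive more
  region-level context. Shipped presets: θ = (0.5, 0.5, 0.85, 0.95)
  (INbreast flavour) and (0.25, 0.25, 0.85, 0.95) (CBIS flavour).
- **SR-/SD-ASP**: focal loss whose υ is a per-sample lookup — (0.25, 0.5)
  for the small/large ratio groups, (0.2, 0.25, 0.3, 0.35) for density
  categories 1–4. Easy pixels in easy samples are down-weighted hardest.

### Preset ambiguities, resolved as configuration

The reported initial weights "0.125 and 0.25" pair one value per dataset in
the source experiments; both readings ship as presets (`inbreast`: both
I = 0.125; `cbis`: both I = 0.25) rather than guessing a single split. The
per-term γ values are only quoted as lying in [0.25, 0.35]; the presets use
the endpoints (γ_dice = 0.25, γ_bce = 0.35) — an explicit guess, marked
here. The pixel hybrid α appears both as 1 (generic setting) and as 2 / 2.5
(D-ASP experiments); the `hybrid` preset keeps α = β = 1 and the dataset
presets carry α = 2 and 2.5.

## Metrics

DSC, relative area difference ΔA, sensitivity and accuracy from per-image
confusion counts, aggregated as an unweighted mean over images (macro);
pooled-pixel micro aggregation is available. Degenerate conventions: both
masks empty → DSC = sensitivity = 1, ΔA = 0; empty ground truth with a
non-empty prediction → DSC = 0 and sensitivity/ΔA undefined, excluded from
their means. Binarization threshold 0.5, configurable. Report tables use the
×100 scale.

## Synthetic phantoms

The generator reproduces the two data properties the losses react to, not
mammography itself:

- **Ratio distribution**: log-normal (μ = −3.5, σ = 0.8) truncated to
  [0.002, 0.35] — median ≈ 3% with a long right tail, qualitatively matching
  the strongly right-skewed clinical ratio distributions. A Gaussian-mixture
  option plants bimodal populations for grouping-recovery tests.
- **Mass geometry**: one mass per image (the per-sample ratio r_i must be
  unambiguous) — a rotated ellipse with eccentricity up to 3, boundary
  perturbed by three low-frequency radial harmonics (amplitude 0.12). The
  rasterized area is calibrated to the drawn target ratio by bisection on a
  radial scale factor; the recorded ratio is recomputed exactly from the
  final mask.
- **Density realization**: category c ∈ {1..4} lowers the mass/background
  contrast gap (0.35, 0.28, 0.20, 0.12) and raises background texture
  amplitude (0.04, 0.07, 0.10, 0.14) with coarser blur (σ = 1.5…3.0 px) on a
  0.35 base level. This is an operational "harder segmentation" proxy, not a
  radiological model: passing tests demonstrate that the machinery reacts
  correctly to ratio and density signals, not clinical performance.

Images are clipped to [0,1]; the clipped fraction stays below 5% by
construction of the amplitudes. What the phantoms do *not* emulate: multi-view
geometry, calcifications, pectoral muscle, annotation noise, or inter-mass
correlation structure — conclusions about real mammograms require real data.

## Training harness

A three-level U-Net (16 base channels by default, an 8-channel variant for
quick runs) with average-pool downsampling, nearest-neighbour upsampling and
skip concatenations, built on the package's reverse-mode autodiff core
(NumPy arrays, im2col convolutions). He initialization from a seeded
generator; the output bias starts at −2 — the logit of a small foreground
prior — the usual initialization when foreground pixels are rare, which lets
early training focus on shaping the foreground score rather than unlearning
a 50% prior. Optimizer: Adam at learning rate 1e−4 and batch size 4; the
rate and batch size are the reference training setting, the choice of Adam
is this package's own. ASP losses are computed per sample with that
sample's metadata and averaged over the batch; the batch loss is therefore
invariant to permuting samples within a batch. Model selection keeps the
best validation-DSC parameters when a validation split is held out. A 5-fold
cross-validation helper is provided; the tests use a single split.

Desk-scale problem sizes used by the test suite: 200 phantoms at 64×64 for
smoke training (5 epochs), 16×16 instances for oracle and gradient checks.
These sizes make the full suite runnable on a single CPU core in minutes
while exercising every code path; they are not calibrated to reproduce any
benchmark number, which would require the restricted clinical datasets and
GPU-scale training of the full attention U-Net baseline.

## Numerical choices

- Probability clamp 1e−7 in all logarithmic losses (BCE, focal).
- Dice smoothing ϵ = 1.0 (configurable); division-free degenerate behaviour.
- RMI regularization as above; logdet failures raise a diagnostic error
  rather than returning NaN.
- Gradient correctness is enforced by tests: every registered loss matches
  central finite differences at randomly chosen pixels (tolerance 1e−3 on
  16×16 instances), and every autodiff primitive is finite-difference
  checked in isolation.
- Exact 1-D k-means by DP (O(k·n²)); ties and boundaries documented above.

## Known limitations

- The RMI term is a lower-bound surrogate; its absolute value depends on the
  region size, pooling and ε, so only comparisons under a fixed config are
  meaningful.
- The learned LR-ASP weighting sees only the ground-truth mask (as in the
  original formulation); it cannot react to image appearance.
- The autodiff core implements exactly the primitives this package needs; it
  is not a general deep-learning framework, and the U-Net is a deliberately
  small stand-in rather than a competitive segmentation architecture.
- Phantom realism limits are listed above; headline clinical metrics are out
  of scope.
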