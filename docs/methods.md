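# Methods

## The problem

Slide-level diagnosis from gigapixel pathology images is usually trained with
multiple instance learning (MIL): each slide is a *bag* of patch feature
vectors `z_1..z_K`, only the slide label is observed, and a slide is abnormal
iff at least one patch is. Attention-based MIL pools patches with learned
softmax weights, but with only slide labels the supervision signal is weak:
on small cohorts training is unstable and the attention often fixates on
irrelevant tissue.

In practice pathologists *can* annotate lesions on some slides — coarsely, or
on a subset. This package implements **rank induction**: a way to inject such
partial annotations into attention-MIL as pairwise ranking constraints, plus
**attention thresholding** to stop large bags from diluting the pooled slide
representation.

## Model

Per bag, a two-layer tanh attention head scores each patch,

    s_k = w' tanh(V z_k + b),        a = softmax(s),

optionally gated (`tanh * sigmoid`, off by default — the plain variant is the
standard attention-MIL baseline skeleton). Weights below `T/K` (T times the
uniform weight) are zeroed and the survivors renormalized,

    abar_k = a_k 1[a_k >= T/K] / sum_j a_j 1[a_j >= T/K],

the bag embedding is `M = sum_k abar_k z_k` and a logistic head gives the
slide probability `p`.

### Rank loss

For a slide with trusted patch labels `y`, the valid pair set is
`P = {(i, j) : y_i = 1, y_j = 0}` (same-class pairs excluded). Each pair's
preference is a RankNet-style sigmoid with a margin,

    P_ij = sigmoid(sigma (s_i - s_j - m)),

applied to the **raw** scores `s` (pre-softmax, so the softmax normalization
constraint cannot absorb the ranking signal). The ground-truth preference of
a valid pair is identically 1, so the pairwise cross-entropy reduces to
`-log P_ij`, computed as `softplus(-x)`; the general two-term BCE is
implemented so that the reduction is a tested fact, not an assumption. The
training objective per slide is

    L = L_BCE(p, slide label) + lambda * L_rank,

with the rank term present only on slides that are annotated *and* contain a
positive patch; negative slides and unannotated positive slides contribute
BCE alone. That asymmetry is why the data model distinguishes
`patch_labels=None, annotated=False` ("not annotated") from all-zero labels
("annotated, no lesion") — collapsing the two would silently apply wrong
constraints.

On large bags up to 1024 annotated and 1024 unannotated patches are sampled
per slide and paired as a full Cartesian product (the instance *sets* are
sampled, not pairs). When class counts are within the caps the sampled loss
equals the exhaustive mean exactly; the tests also verify the sampling is
unbiased.

### Parameter defaults (and why)

| parameter | default | meaning |
|---|---|---|
| `margin` m | 1 | score gap where a pair's preference crosses 0.5 |
| `scale` sigma | 1 | sigmoid sharpness; m and sigma inside/outside so they are not degenerate |
| `rank_weight` lambda | 1 | rank-loss weight; 0 recovers the AB-MIL baseline |
| `threshold` T | 1 | cutoff T/K, i.e. suppress below-uniform attention |
| `hidden_dim` | 256 | attention layer width |
| caps | 1024/1024 | per-slide pair-sampling caps |
| `lr`, `weight_decay` | 2e-4, 1e-5 | Adam settings |
| `max_epochs`, `patience`, `warmup_epochs` | 200, 7, 20 | early stopping on validation total loss |

These mirror the training protocol the method was developed with; they are
exposed, not hard-coded.

## Numerical choices

- **Thresholding semantics.** The cutoff is *relative*: `T/K`, T times the
  uniform weight. Softmax weights are at most 1 and typically ~1/K, so an
  absolute cutoff around 1 would zero everything; the relative reading makes
  the useful sweep `T in {0, 0.25, 0.5, 1, 2, 5}` meaningful. The boundary is
  inclusive (a weight exactly at `T/K` survives — so a uniform bag at T=1 is
  unchanged). If nothing survives, the argmax weight alone is kept (training
  must never divide by zero, e.g. at T=5 with concentrated attention); ties
  break to the lowest index. The operator is idempotent. Thresholding is
  applied during training and, by default, at inference
  (`apply_threshold_at_inference=False` restores train-only behaviour).
- **Straight-through indicator.** Under differentiation the survival
  indicator is a constant: gradients flow through surviving weights only.
  This is the simplest consistent subgradient; a finite-difference test
  verifies the full backward pass (including this path and the rank-loss path
  into raw scores) to 1e-4.
- **No autodiff framework.** The network is a few small dense maps, so the
  gradients are hand-derived numpy and the optimizer is a ~30-line Adam
  (L2-style weight decay folded into the gradient). This keeps the package
  dependency-light and CPU-friendly.
- **Early stopping.** The monitor arms at the first epoch after the 20-epoch
  warmup (that epoch's validation loss is the baseline) and stops after 7
  consecutive non-improving epochs; with a flat validation loss from epoch 21
  training stops at epoch 28. The restored checkpoint is the *global* best
  validation loss, tracked independently of the monitor. Validation loss is
  the full objective L (BCE-only on slides without rank pairs), matching what
  is optimized.
- **Stability.** `-log sigmoid(x)` is computed as `softplus(-x)` via
  `logaddexp`; softmax subtracts the max; BCE clamps p at 1e-7.
- **Batching.** Bags vary in K, so the optimization unit is one slide
  (batch = 1); per-slide pair averages are averaged across slides.

## Tissue masking

`tissue_mask` runs multilevel Otsu (default 3 classes) on the grayscale
image. Rather than always cutting below the top class, the tissue/background
cut is the multi-Otsu candidate with **maximal binary between-class
variance**: on a bimodal image this is exactly the 2-class Otsu threshold
(the naive top cut would split whichever mode the extra class subdivides —
verified to misclassify ~a third of a disc-on-white image), while on a
trimodal stained-tissue histogram (nuclei / cytoplasm / glass) the
tissue-vs-glass cut wins. Images with too few gray values degrade to fewer
classes; constant images give an empty mask with a warning. Tiles are
half-open `[x0, x0+patch)`, 0-based, row-major; tiles with tissue coverage
`>= 5%` are kept (inclusive boundary — "less than 5%" is discarded). A patch
is labeled positive on strictly positive intersection area with the
annotation polygons (a configurable minimum-overlap fraction exists, default
0). Polygon coarsening is a Minkowski buffer; on the synthetic grid it is a
Chebyshev dilation by whole patch-widths. Cross-magnification scaling (e.g.
annotation pixels drawn at twice the tiling resolution) is a factor of 2 the
caller applies; the module itself is magnification-agnostic.

## Synthetic data: what it emulates, what it does not

`SyntheticSpec` draws bags from a Gaussian mean-shift model: instances are
`N(0, I)` in D=32 dimensions; in positive bags a contiguous grid blob of
2-10% of patches is shifted by `separation * u` along a fixed unit direction
`u`. Defaults: 30+30 training slides, 10+10 validation, 20+20 test, bag
sizes 100-300, separation 2.0. The defaults are chosen so the *instance*
problem is genuinely noisy (Bayes error `Phi(-1) ~ 0.16` per instance along
the optimal projection) while a correct attention policy makes the *bag*
problem learnable in minutes on one CPU — the regime where annotation
guidance should matter.

The generator reproduces three stress regimes: stratified training-set
subsampling (low data), Chebyshev dilation of patch labels (coarse
annotations), and hiding patch labels on all but a fraction f of positive
slides (subset annotation; exactly `round(f * n_pos)` keep labels, e.g.
18 of 89 at f=0.2).

One behaviour of this world is worth flagging: dilating the patch labels can
*improve* slide AUROC rather than degrade it. A pad of one patch-width grows
a 2-10% lesion blob roughly ninefold, multiplying the valid ranking pairs;
the extra "falsely positive" patches are ordinary normal instances, and
ranking them above other normals costs little while the added pairs
stabilize training (the test suite measures this). Real slides do not share
the artifact — tissue adjacent to a lesion is genuinely confusable — so
coarsening experiments on this generator probe pair-count effects, not
annotation noise per se.

What a green test on this data does **not** establish: real WSI bags have
correlated, non-Gaussian features from a pretrained encoder, lesion
morphology and staining variation, and bag sizes in the tens of thousands.
The synthetic results demonstrate the *mechanism* — ranking supervision
steering attention and stabilizing training — not clinical performance
numbers.

## Evaluation protocol

AUROC is the Mann-Whitney rank statistic (ties half-counted), AUPRC is
step-interpolated average precision, accuracy is at 0.5. Localization uses
the top-alpha% protocol: rank patches by attention, select
`max(1, round(alpha/100 * n_tumor))` (round-half-even; attention ties break
to the lower index), and score IoU, Dice and pointing-game hit against the
annotated patches; slides without annotated tumor patches are excluded with
a warning. Ranking uses the pre-threshold softmax weights by default:
thresholding only zeroes and renormalizes, so the ranking among survivors is
preserved, and alpha-sweeps stay well-defined when T zeroes many patches.
Since `round(alpha/100 * n_tumor) <= n_tumor` for alpha <= 100, selecting
from all patches and capping at `n_tumor` coincide on the standard alpha
grid {1, 5, 10, 20, 50, 75, 100}. Monte Carlo cross-validation resplits
train/validation only; the test set stays fixed.

## Experiments module

`run_experiment` sweeps one design factor with freshly trained models per
grid point and fold: training fraction (stratified subsample — stratification
avoids degenerate all-negative subsets at 20%), label dilation, annotation
fraction, or threshold T. The T-ablation additionally reports the mean
thresholded-attention mass on non-lesion patches of positive test slides —
the dilution quantity thresholding is meant to suppress.

## Known limitations

- Features are expected pre-extracted; no pyramidal WSI readers, stain
  normalization, or pretrained encoders (the CLI's `preprocess` uses a
  mean-pooled-pixel stand-in feature and says so).
- Single-branch attention only; no multi-branch or transformer aggregators.
- The hand-rolled trainer is single-threaded CPU; it is sized for
  hundreds-of-slides cohorts with pre-extracted features, not for
  end-to-end encoder training.
- Per-instance gradients treat the threshold indicator as locally constant;
  extremely aggressive thresholds (T >> K * max a) fall back to one-hot
  pooling where the BCE gradient into the attention head vanishes (the rank
  loss still provides signal on annotated slides).
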