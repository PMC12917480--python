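"""The rank-induction objective.

Partial expert annotations enter the model as pairwise ranking constraints on
the *raw* attention scores (pre-softmax, so the constraint is not distorted by
the normalization): an annotated (lesion) patch i should out-score every
unannotated patch j of the same slide. Following the RankNet construction
with a margin, the preference probability for a pair is

    P_ij = sigmoid(sigma * (s_i - s_j - m))

so ``m`` is the score gap at which P_ij = 0.5 and ``sigma`` sharpens the
transition. The valid pair set is P = {(i, j) | y_i = 1, y_j = 0} (same-class
pairs excluded); its ground-truth preference is identically 1, so the
cross-entropy against it reduces to -log P_ij, computed stably as
softplus(-x). The slide loss is

    L = L_BCE(p, slide_label) + lambda * L_rank

with the rank term included only for slides whose annotations are trusted and
contain at least one lesion patch; negative and unannotated slides contribute
the slide-level BCE alone.

To bound memory on huge bags, up to ``max_pos_samples`` annotated and
``max_neg_samples`` unannotated patches are sampled per slide (without
replacement) and the full Cartesian product of the two samples forms the
pairs; when the class counts are within the caps the sampled loss equals the
exhaustive one exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "RankLossConfig",
    "RankLossResult",
    "pairwise_preference",
    "rank_loss",
    "slide_bce",
    "total_loss",
]

_P_CLAMP = 1e-7


@dataclass
class RankLossConfig:
    """Hyperparameters of the pairwise rank loss.

    margin: score separation m at which a pair's preference crosses 0.5.
    scale: sigmoid sharpness sigma > 0.
    weight: loss weight lambda >= 0 in L = L_BCE + lambda * L_rank.
    max_pos_samples / max_neg_samples: per-slide caps on sampled annotated /
        unannotated patches (pairs are the Cartesian product of the samples).
    """

    margin: float = 1.0
    scale: float = 1.0
    weight: float = 1.0
    max_pos_samples: int = 1024
    max_neg_samples: int = 1024

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale sigma must be > 0")
        if self.weight < 0:
            raise ValueError("weight lambda must be >= 0")
        if self.max_pos_samples < 1 or self.max_neg_samples < 1:
            raise ValueError("sampling caps must be >= 1")


@dataclass
class RankLossResult:
    loss: float
    pairs_used: int
    skipped: bool
    grad: np.ndarray | None = None


def pairwise_preference(s_i, s_j, margin: float = 1.0, scale: float = 1.0):
    """P_ij = sigmoid(scale * (s_i - s_j - margin)); P_ij = 0.5 at s_i - s_j = margin."""
    return expit(scale * (np.asarray(s_i, dtype=float) - np.asarray(s_j, dtype=float) - margin))


def _softplus(x: np.ndarray) -> np.ndarray:
    # -log sigmoid(x) = softplus(-x), overflow-safe
    return np.logaddexp(0.0, x)


def rank_loss(
    s: np.ndarray,
    y: np.ndarray,
    config: RankLossConfig | None = None,
    rng: np.random.Generator | None = None,
    with_grad: bool = False,
    target_preference: float = 1.0,
) -> RankLossResult:
    """Mean pairwise BCE over sampled (annotated, unannotated) score pairs.

    ``target_preference`` is the ground-truth preference P-bar of a valid
    pair; for the valid pair set it is 1 by construction, in which case the
    two-term BCE reduces to -log P_ij. Returns loss 0 with ``skipped=True``
    when no valid pair exists (all patches the same class).
    """
    if config is None:
        config = RankLossConfig()
    s = np.asarray(s, dtype=float)
    y = np.asarray(y)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        grad = np.zeros_like(s) if with_grad else None
        return RankLossResult(0.0, 0, True, grad)
    if rng is None:
        rng = np.random.default_rng()
    if len(pos) > config.max_pos_samples:
        pos = rng.choice(pos, size=config.max_pos_samples, replace=False)
    if len(neg) > config.max_neg_samples:
        neg = rng.choice(neg, size=config.max_neg_samples, replace=False)

    x = config.scale * (s[pos][:, None] - s[neg][None, :] - config.margin)
    n_pairs = x.size
    pbar = float(target_preference)
    # BCE(P-bar, P) = -P-bar log P - (1 - P-bar) log(1 - P), in softplus form
    loss_mat = pbar * _softplus(-x) + (1.0 - pbar) * _softplus(x)
    loss = float(loss_mat.mean())
    grad = None
    if with_grad:
        # dBCE/dx = sigmoid(x) - P-bar; chain through x = scale*(s_i - s_j - m)
        dx = (expit(x) - pbar) * (config.scale / n_pairs)
        grad = np.zeros_like(s)
        np.add.at(grad, pos, dx.sum(axis=1))
        np.add.at(grad, neg, -dx.sum(axis=0))
    return RankLossResult(loss, n_pairs, False, grad)


def slide_bce(p: float, label: int) -> float:
    """Slide-level binary cross-entropy, with p clamped to [1e-7, 1 - 1e-7]."""
    p = float(np.clip(p, _P_CLAMP, 1.0 - _P_CLAMP))
    label = int(label)
    return float(-(label * np.log(p) + (1 - label) * np.log(1.0 - p)))


def total_loss(
    bag,
    p: float,
    raw_scores: np.ndarray,
    config: RankLossConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """L = L_BCE + lambda * L_rank for one bag.

    The rank term is applied only when the bag's annotations are trusted
    (``bag.annotated``) and at least one patch is labeled positive; negative
    slides and unannotated positive slides get the slide-level BCE alone.
    Returns a components dict: bce, rank, total, pairs_used, rank_skipped.
    """
    if config is None:
        config = RankLossConfig()
    bce = slide_bce(p, bag.slide_label)
    use_rank = (
        config.weight > 0
        and bag.annotated
        and bag.patch_labels is not None
        and bool(np.any(bag.patch_labels == 1))
    )
    if use_rank:
        res = rank_loss(raw_scores, bag.patch_labels, config, rng=rng)
        rank = res.loss
        pairs, skipped = res.pairs_used, res.skipped
    else:
        rank, pairs, skipped = 0.0, 0, True
    return {
        "bce": bce,
        "rank": rank,
        "total": bce + config.weight * rank,
        "pairs_used": pairs,
        "rank_skipped": skipped,
    }
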