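"""Synthetic MIL bag generator.

Emulates feature bags from tiled pathology slides with a Gaussian mean-shift
instance model: normal patches are draws from an isotropic D-dimensional
normal, lesion patches get an additional shift of ``separation`` along a fixed
unit direction (one direction per dataset). Because the Bayes-optimal
instance discriminant is the projection onto that direction, localization and
attention behaviour have analytic oracles — e.g. the per-instance error of
the optimal linear rule is Phi(-separation/2).

Patches live on a virtual square grid and positive bags place their lesion as
a spatially contiguous blob (nearest cells in Chebyshev distance around a
random centre), so coarsening annotations by grid dilation is meaningful.

Three stress regimes are reproducible from the same generator: shrinking the
number of training slides (low-data), dilating the patch labels
(annotation-granularity), and hiding the annotations of a fraction of
positive slides (subset-annotated setting).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .bags import Bag

__all__ = [
    "SyntheticSpec",
    "generate_bag",
    "generate_dataset",
    "coarsen_labels",
    "subset_annotation",
]


@dataclass
class SyntheticSpec:
    """Generative parameters for a synthetic bag dataset.

    Defaults are sized for minutes-level CPU experiments: 30 slides per class
    in train (60 total), 10 per class in val, 20 per class in test, bag sizes
    100-300, 32-d features, separation 2.0 (per-instance Bayes error
    Phi(-1) ~ 0.16, so bags are learnable but not trivially separable), and
    lesion fractions of 2-10%% of patches in positive bags.
    """

    n_train_per_class: int = 30
    n_val_per_class: int = 10
    n_test_per_class: int = 20
    bag_size_range: tuple[int, int] = (100, 300)
    lesion_fraction_range: tuple[float, float] = (0.02, 0.10)
    feature_dim: int = 32
    separation: float = 2.0
    noise_scale: float = 1.0
    annotated_fraction: float = 1.0
    coarsening_pad: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("lesion fractions must lie strictly inside (0, 1)")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ValueError("annotated_fraction must be in [0, 1]")
        if self.bag_size_range[0] < 1 or self.bag_size_range[0] > self.bag_size_range[1]:
            raise ValueError("invalid bag size range")

    def lesion_direction(self) -> np.ndarray:
        """The dataset's fixed unit shift direction (derived from the seed)."""
        rng = np.random.default_rng(self.seed + 1_000_003)
        u = rng.normal(size=self.feature_dim)
        return u / np.linalg.norm(u)


def _grid_coords(n: int) -> np.ndarray:
    """Row-major (row, col) coordinates of n cells on the smallest square grid."""
    side = int(np.ceil(np.sqrt(n)))
    rows, cols = np.divmod(np.arange(n), side)
    return np.stack([rows, cols], axis=1)


def _contiguous_blob(coords: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Indices of a Chebyshev-compact blob of ``size`` cells around a random centre."""
    centre = coords[rng.integers(len(coords))]
    cheb = np.max(np.abs(coords - centre), axis=1)
    order = np.lexsort((np.arange(len(coords)), cheb))  # distance, then index
    return order[:size]


def generate_bag(spec: SyntheticSpec, label: int, rng: np.random.Generator, slide_id: str = "synthetic") -> Bag:
    """Draw one bag; positive bags always contain at least one lesion patch."""
    k = int(rng.integers(spec.bag_size_range[0], spec.bag_size_range[1] + 1))
    features = rng.normal(0.0, spec.noise_scale, size=(k, spec.feature_dim))
    coords = _grid_coords(k)
    y = np.zeros(k, dtype=np.int8)
    if label == 1:
        frac = rng.uniform(*spec.lesion_fraction_range)
        n_lesion = max(1, int(round(frac * k)))
        blob = _contiguous_blob(coords, n_lesion, rng)
        features[blob] += spec.separation * spec.lesion_direction()
        y[blob] = 1
    return Bag(
        slide_id=slide_id,
        features=features.astype(np.float32),
        slide_label=int(label),
        patch_labels=y,
        patch_coords=coords,
        annotated=True,
    )


def generate_dataset(spec: SyntheticSpec) -> dict[str, list[Bag]]:
    """Generate train/val/test bag lists; deterministic given ``spec.seed``.

    Training positives are subset-annotated per ``spec.annotated_fraction``
    and coarsened by ``spec.coarsening_pad``; val/test keep exact labels so
    localization is always evaluable.
    """
    rng = np.random.default_rng(spec.seed)
    splits: dict[str, list[Bag]] = {}
    for split, n_per_class in (
        ("train", spec.n_train_per_class),
        ("val", spec.n_val_per_class),
        ("test", spec.n_test_per_class),
    ):
        bags = []
        for label in (1, 0):
            for i in range(n_per_class):
                bags.append(generate_bag(spec, label, rng, slide_id=f"{split}_{'pos' if label else 'neg'}_{i:03d}"))
        splits[split] = bags
    if spec.coarsening_pad > 0:
        splits["train"] = [
            coarsen_labels(b, spec.coarsening_pad) if b.slide_label == 1 else b
            for b in splits["train"]
        ]
    if spec.annotated_fraction < 1.0:
        splits["train"] = subset_annotation(splits["train"], spec.annotated_fraction, seed=spec.seed + 7)
    return splits


def coarsen_labels(bag: Bag, pad_patches: int) -> Bag:
    """Dilate patch labels by a Chebyshev radius on the bag's virtual grid.

    Emulates coarse expert annotations: every patch within ``pad_patches``
    grid steps (chessboard distance) of a labeled patch becomes labeled.
    Original positives stay positive; pad 0 is the identity.
    """
    if pad_patches < 0:
        raise ValueError("pad_patches must be >= 0")
    if bag.patch_coords is None:
        raise ValueError("coarsen_labels requires patch_coords")
    if bag.patch_labels is None or pad_patches == 0 or not bag.patch_labels.any():
        return replace(bag)
    pos = bag.patch_coords[bag.patch_labels == 1]
    # chessboard distance from every patch to the nearest labeled patch
    d = np.abs(bag.patch_coords[:, None, :] - pos[None, :, :]).max(axis=2).min(axis=1)
    return replace(bag, patch_labels=(d <= pad_patches).astype(np.int8))


def subset_annotation(bags: list[Bag], fraction: float, seed: int) -> list[Bag]:
    """Keep annotations on exactly round(fraction * n_pos) positive slides.

    The remaining positive slides have their patch labels withheld
    (``patch_labels=None``, ``annotated=False``) — not zeroed — so the trainer
    can tell "not annotated" from "no lesion". Negative slides are untouched.
    Rounding is round-half-even (numpy). Deterministic given ``seed``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    pos_idx = [i for i, b in enumerate(bags) if b.slide_label == 1]
    n_keep = int(np.round(fraction * len(pos_idx)))
    keep = set(rng.permutation(pos_idx)[:n_keep].tolist())
    out = []
    for i, b in enumerate(bags):
        if b.slide_label == 1 and i not in keep:
            out.append(replace(b, patch_labels=None, annotated=False))
        else:
            out.append(replace(b))
    return out
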