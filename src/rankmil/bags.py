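"""Feature bags, slide manifests, and their on-disk formats.

A *bag* is one slide's worth of instances: a dense ``K x D`` matrix of patch
feature vectors plus a binary slide label. Positive slides may additionally
carry per-patch binary labels (``y_k = 1`` iff the patch overlaps an
expert-annotated region) and the grid coordinates of each patch. The
``annotated`` flag distinguishes "no lesion" (negative slide, all-zero labels)
from "lesion present but not annotated" (positive slide, labels withheld).

Bags are stored one HDF5 file per slide (bags vary in K, so per-slide files
allow lazy loading); manifests are plain CSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Bag",
    "Manifest",
    "BagValidationError",
    "write_bag",
    "read_bag",
    "load_manifest",
    "save_manifest",
    "split_manifest",
    "load_bags",
]

MANIFEST_COLUMNS = ["slide_id", "path", "label", "annotated", "split"]


class BagValidationError(ValueError):
    """A bag violates one of its structural invariants."""


@dataclass
class Bag:
    """One slide: instance features, slide label, optional patch labels.

    Parameters
    ----------
    slide_id : str
        Unique slide identifier.
    features : ndarray of shape (K, D)
        Per-patch feature vectors; must be finite.
    slide_label : int
        1 = abnormal, 0 = normal. A slide is positive iff >= 1 patch is.
    patch_labels : ndarray of shape (K,), optional
        Binary patch labels; ``y_k = 1`` iff patch k overlaps an annotated
        region. ``None`` when no annotation exists for the slide.
    patch_coords : ndarray of shape (K, 2), optional
        (row, col) grid position of each patch.
    annotated : bool
        Whether ``patch_labels`` are trusted expert annotations for this
        slide. Unannotated positive slides carry ``patch_labels=None`` and
        ``annotated=False``, never all-zeros.
    """

    slide_id: str
    features: np.ndarray
    slide_label: int
    patch_labels: np.ndarray | None = None
    patch_coords: np.ndarray | None = None
    annotated: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.patch_labels is not None:
            self.patch_labels = np.asarray(self.patch_labels).astype(np.int8)
        if self.patch_coords is not None:
            self.patch_coords = np.asarray(self.patch_coords)
        self.slide_label = int(self.slide_label)
        self.validate()

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def validate(self) -> None:
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise BagValidationError(
                f"features must be a K x D matrix with K >= 1, got shape "
                f"{self.features.shape}"
            )
        if not np.all(np.isfinite(self.features)):
            raise BagValidationError("features contain non-finite values")
        if self.slide_label not in (0, 1):
            raise BagValidationError(f"slide_label must be 0 or 1, got {self.slide_label}")
        if self.patch_labels is not None:
            if self.patch_labels.shape != (self.n_patches,):
                raise BagValidationError(
                    f"patch_labels length {self.patch_labels.shape} does not match "
                    f"K={self.n_patches}"
                )
            if not np.isin(self.patch_labels, [0, 1]).all():
                raise BagValidationError("patch_labels must be binary")
            if self.slide_label == 0 and self.patch_labels.any():
                raise BagValidationError(
                    "negative slide (slide_label=0) has a positive patch_label"
                )
        if self.patch_coords is not None and self.patch_coords.shape != (self.n_patches, 2):
            raise BagValidationError(
                f"patch_coords shape {self.patch_coords.shape} does not match (K, 2)"
            )


def write_bag(bag: Bag, path: str | os.PathLike) -> None:
    """Write a bag to a single HDF5 container file.

    Layout: datasets ``/features`` (native float dtype preserved, so the
    round trip is bit-exact), optional ``/patch_labels`` (int8) and
    ``/coords`` (int64); attrs ``slide_id``, ``slide_label``, ``annotated``.
    """
    bag.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features)
        if bag.patch_labels is not None:
            f.create_dataset("patch_labels", data=bag.patch_labels.astype(np.int8))
        if bag.patch_coords is not None:
            f.create_dataset("coords", data=bag.patch_coords.astype(np.int64))
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["slide_label"] = int(bag.slide_label)
        f.attrs["annotated"] = bool(bag.annotated)


def read_bag(path: str | os.PathLike) -> Bag:
    """Read a bag container file; raises on any invariant violation."""
    if not Path(path).exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise BagValidationError(f"{path}: missing /features dataset")
        features = f["features"][...]
        patch_labels = f["patch_labels"][...] if "patch_labels" in f else None
        coords = f["coords"][...] if "coords" in f else None
        return Bag(
            slide_id=str(f.attrs.get("slide_id", Path(path).stem)),
            features=features,
            slide_label=int(f.attrs["slide_label"]),
            patch_labels=patch_labels,
            patch_coords=coords,
            annotated=bool(f.attrs.get("annotated", patch_labels is not None)),
        )


@dataclass
class Manifest:
    """Table of slides: slide_id, bag file path, label, annotated flag, split."""

    entries: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=MANIFEST_COLUMNS))

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.entries["slide_id"].duplicated().any():
            dupes = self.entries.loc[self.entries["slide_id"].duplicated(), "slide_id"]
            raise ValueError(f"duplicate slide_ids in manifest: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, split: str) -> "Manifest":
        return Manifest(self.entries[self.entries["split"] == split].reset_index(drop=True))


def load_manifest(path: str | os.PathLike, check_paths: bool = True) -> Manifest:
    df = pd.read_csv(path, dtype={"slide_id": str, "path": str, "split": str})
    m = Manifest(df)
    if check_paths:
        base = Path(path).parent
        for p in df["path"]:
            resolved = Path(p) if os.path.isabs(p) else base / p
            if not resolved.exists():
                raise FileNotFoundError(f"manifest references missing bag file: {p}")
    return m


def save_manifest(manifest: Manifest, path: str | os.PathLike) -> None:
    manifest.entries.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def _largest_remainder(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Integer allocation of n items to splits, exact total, largest remainder."""
    quotas = {k: n * f for k, f in fractions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    shortfall = n - sum(counts.values())
    order = sorted(fractions, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:shortfall]:
        counts[k] += 1
    return counts


def split_manifest(manifest: Manifest, fractions: dict[str, float], seed: int) -> Manifest:
    """Assign split tags by stratified random allocation.

    Fractions must sum to 1. Within each slide-label class the allocation is
    exact to the largest-remainder rounding, so class proportions are
    preserved within one slide per class. Deterministic given ``seed``.
    """
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    df = manifest.entries.copy().reset_index(drop=True)
    split_col = pd.Series(index=df.index, dtype=object)
    for _, idx in df.groupby("label").groups.items():
        idx = np.asarray(sorted(idx))
        perm = rng.permutation(len(idx))
        counts = _largest_remainder(len(idx), fractions)
        start = 0
        for name in fractions:
            take = idx[perm[start : start + counts[name]]]
            split_col.loc[take] = name
            start += counts[name]
    df["split"] = split_col
    return Manifest(df)


def load_bags(manifest: Manifest, split: str | None = None, base_dir: str | os.PathLike = ".") -> list[Bag]:
    """Load all bags of a manifest (optionally one split) into memory."""
    df = manifest.entries if split is None else manifest.subset(split).entries
    bags = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = Path(base_dir) / p
        bags.append(read_bag(p))
    return bags


def hide_annotations(bag: Bag) -> Bag:
    """Return a copy with patch labels withheld (weak supervision only)."""
    return replace(bag, patch_labels=None, annotated=False)
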