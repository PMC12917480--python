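"""Experiment harnesses: low-data, annotation granularity, subset annotation,
threshold ablation, and attention localization.

Each harness takes train/val/test bag lists, sweeps one factor of the study
design, trains one model per grid point and fold, and returns a tidy
DataFrame (one row per grid point x fold) ready to write as CSV:

- ``low_data``: stratified subsampling of the training slides
  (default grid 20/40/60/80/100%).
- ``granularity``: patch labels of annotated positive slides dilated by
  0..n patch-widths before training.
- ``subset_annotation``: only a fraction f of positive training slides keep
  their patch annotations (default grid 5..80% plus the 0/100% anchors).
- ``threshold_ablation``: sweep the attention threshold T; also reports the
  mean cumulative attention weight on non-lesion patches of positive test
  slides (how much mass the model wastes off-lesion).
- ``localization``: IoU / Dice / pointing game of the fitted attention
  against patch labels at each top-alpha%.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bags import Bag
from .estimator import RankInductionClassifier
from .evaluate import DEFAULT_ALPHAS, classification_metrics, localization_report
from .synthetic import coarsen_labels, subset_annotation

__all__ = [
    "run_experiment",
    "subsample_bags",
    "nonlesion_attention_mass",
    "EXPERIMENT_KINDS",
]

LOW_DATA_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)
SUBSET_GRID = (0.05, 0.10, 0.20, 0.40, 0.60, 0.80)
THRESHOLD_GRID = (0.0, 0.25, 0.5, 1.0, 2.0, 5.0)
GRANULARITY_GRID = (0, 1, 2, 3)

EXPERIMENT_KINDS = ("low_data", "granularity", "subset_annotation", "threshold_ablation", "localization")


def subsample_bags(bags: list[Bag], fraction: float, seed: int) -> list[Bag]:
    """Stratified (by slide label) random subsample of a bag list."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1.0:
        return list(bags)
    rng = np.random.default_rng(seed)
    labels = np.array([b.slide_label for b in bags])
    keep: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        n = max(1, int(round(fraction * idx.size)))
        keep.extend(rng.permutation(idx)[:n].tolist())
    return [bags[i] for i in sorted(keep)]


def nonlesion_attention_mass(est: RankInductionClassifier, bags: list[Bag]) -> float:
    """Mean over positive bags of the thresholded attention mass on y=0 patches."""
    masses = []
    for bag in bags:
        if bag.slide_label != 1 or bag.patch_labels is None:
            continue
        state = est.attention(bag)
        masses.append(float(state.thresholded_weights[bag.patch_labels == 0].sum()))
    return float(np.mean(masses)) if masses else float("nan")


def _fit_and_score(train, val, test, seed: int, **params) -> tuple[RankInductionClassifier, dict]:
    est = RankInductionClassifier(random_state=seed, **params)
    est.fit(train, X_val=val)
    p = est.predict_proba(test)[:, 1]
    metrics = classification_metrics(p, [b.slide_label for b in test])
    return est, metrics


def run_experiment(
    kind: str,
    train_bags: list[Bag],
    val_bags: list[Bag],
    test_bags: list[Bag],
    grid=None,
    n_folds: int = 5,
    seed: int = 0,
    estimator_params: dict | None = None,
) -> pd.DataFrame:
    """Run one experiment harness; returns one row per grid point x fold."""
    if kind not in EXPERIMENT_KINDS:
        raise ValueError(f"unknown experiment kind {kind!r}; choose from {EXPERIMENT_KINDS}")
    params = dict(estimator_params or {})
    master = np.random.default_rng(seed)
    fold_seeds = [int(master.integers(0, 2**31 - 1)) for _ in range(n_folds)]
    rows: list[dict] = []

    if kind == "localization":
        alphas = tuple(grid) if grid is not None else DEFAULT_ALPHAS
        for fold, fs in enumerate(fold_seeds):
            est, metrics = _fit_and_score(train_bags, val_bags, test_bags, fs, **params)
            pos = [b for b in test_bags if b.slide_label == 1 and b.patch_labels is not None]
            report = localization_report(
                [est.attention(b).softmax_weights for b in pos],
                [b.patch_labels for b in pos],
                [b.slide_id for b in pos],
                alphas=alphas,
            )
            for _, r in report.summary.iterrows():
                rows.append({"fold": fold, "alpha": r["alpha"], "iou": r["iou"],
                             "dice": r["dice"], "pointing_accuracy": r["pointing_accuracy"],
                             **metrics})
        return pd.DataFrame(rows)

    if grid is None:
        grid = {
            "low_data": LOW_DATA_GRID,
            "granularity": GRANULARITY_GRID,
            "subset_annotation": SUBSET_GRID,
            "threshold_ablation": THRESHOLD_GRID,
        }[kind]

    for value in grid:
        for fold, fs in enumerate(fold_seeds):
            fit_params = dict(params)
            if kind == "low_data":
                if not 0.0 < value <= 1.0:
                    raise ValueError(f"low_data fraction {value} out of range")
                tr = subsample_bags(train_bags, float(value), seed=fs)
            elif kind == "granularity":
                pad = int(value)
                if pad < 0:
                    raise ValueError("granularity pad must be >= 0")
                tr = [coarsen_labels(b, pad) if b.annotated and b.slide_label == 1 else b
                      for b in train_bags]
            elif kind == "subset_annotation":
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"annotation fraction {value} out of range")
                tr = subset_annotation(train_bags, float(value), seed=fs)
            else:  # threshold_ablation
                if value < 0:
                    raise ValueError("threshold T must be >= 0")
                tr = train_bags
                fit_params["threshold"] = float(value)
            est, metrics = _fit_and_score(tr, val_bags, test_bags, fs, **fit_params)
            row = {"kind": kind, "value": value, "fold": fold, "seed": fs,
                   "n_train": len(tr), **metrics}
            if kind == "threshold_ablation":
                row["nonlesion_attention"] = nonlesion_attention_mass(est, test_bags)
            rows.append(row)
    return pd.DataFrame(rows)
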