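"""Slide-level classification metrics and attention-localization metrics.

Localization follows the top-alpha% protocol: patches are ranked by attention
weight and the top ``max(1, round(alpha/100 * n_tumor))`` are selected, where
``n_tumor`` is the number of tumor-annotated patches in that slide — so a
perfect attention map reaches IoU = Dice = 1 at alpha = 100. The pointing
game scores a slide as a hit if at least one selected patch lies inside the
annotated region; pointing accuracy is hits / (hits + misses) over positive
slides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, average_precision_score, roc_auc_score

__all__ = [
    "DEFAULT_ALPHAS",
    "LocalizationReport",
    "select_top_patches",
    "localization_scores",
    "localization_report",
    "classification_metrics",
    "monte_carlo_cv",
]

DEFAULT_ALPHAS = (1, 5, 10, 20, 50, 75, 100)


def select_top_patches(attention: np.ndarray, n_tumor: int, alpha: float) -> np.ndarray:
    """Indices of the top max(1, round(alpha/100 * n_tumor)) attention patches.

    Rounding is round-half-even; ties in attention break toward the lower
    index (stable sort), so selection is deterministic.
    """
    if n_tumor < 1:
        raise ValueError("n_tumor must be >= 1 (slides without tumor patches are excluded)")
    attention = np.asarray(attention, dtype=float)
    n_sel = max(1, int(np.round(alpha / 100.0 * n_tumor)))
    n_sel = min(n_sel, attention.size)
    order = np.argsort(-attention, kind="stable")
    return np.sort(order[:n_sel])


def localization_scores(selected, tumor) -> tuple[float, float, bool]:
    """(IoU, Dice, hit) between a selected index set and the tumor index set."""
    selected, tumor = set(np.asarray(selected).tolist()), set(np.asarray(tumor).tolist())
    if not tumor:
        raise ValueError("empty tumor set: slide excluded from localization")
    inter = len(selected & tumor)
    iou = inter / len(selected | tumor)
    dice = 2.0 * inter / (len(selected) + len(tumor))
    return iou, dice, inter >= 1


@dataclass
class LocalizationReport:
    """Per-slide and aggregate localization metrics over an alpha grid."""

    per_slide: pd.DataFrame
    alphas: tuple = DEFAULT_ALPHAS
    n_excluded: int = 0

    @property
    def summary(self) -> pd.DataFrame:
        """Mean IoU/Dice and pointing accuracy per alpha over positive slides."""
        g = self.per_slide.groupby("alpha")
        out = g[["iou", "dice"]].mean()
        out["pointing_accuracy"] = g["hit"].mean()
        return out.reset_index()

    def pointing_accuracy(self, alpha: float) -> float:
        rows = self.per_slide[self.per_slide["alpha"] == alpha]
        return float(rows["hit"].mean())


def localization_report(
    attentions: list[np.ndarray],
    patch_labels: list[np.ndarray],
    slide_ids: list[str] | None = None,
    alphas=DEFAULT_ALPHAS,
) -> LocalizationReport:
    """Score attention maps of positive slides against their patch labels.

    Slides with no tumor-annotated patch are excluded with a warning.
    """
    if slide_ids is None:
        slide_ids = [f"slide_{i}" for i in range(len(attentions))]
    rows = []
    n_excluded = 0
    for sid, att, y in zip(slide_ids, attentions, patch_labels):
        y = np.asarray(y)
        tumor = np.flatnonzero(y == 1)
        if tumor.size == 0:
            n_excluded += 1
            warnings.warn(f"{sid}: no tumor-annotated patches; excluded from localization")
            continue
        for alpha in alphas:
            sel = select_top_patches(att, tumor.size, alpha)
            iou, dice, hit = localization_scores(sel, tumor)
            rows.append(
                {"slide_id": sid, "alpha": alpha, "n_tumor": tumor.size,
                 "n_selected": sel.size, "iou": iou, "dice": dice, "hit": hit}
            )
    return LocalizationReport(pd.DataFrame(rows), tuple(alphas), n_excluded)


def classification_metrics(scores, labels) -> dict[str, float]:
    """AUROC (Mann-Whitney rank statistic, ties half-counted), AUPRC (step
    interpolation), and accuracy at threshold 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("AUROC/AUPRC undefined: labels contain a single class")
    return {
        "auroc": float(roc_auc_score(labels, scores)),
        "auprc": float(average_precision_score(labels, scores)),
        "accuracy": float(accuracy_score(labels, scores >= 0.5)),
    }


def monte_carlo_cv(
    bags: list,
    test_bags: list,
    make_estimator,
    n_folds: int = 10,
    val_fraction: float = 0.25,
    seed: int = 0,
    extra_metrics=None,
) -> pd.DataFrame:
    """Monte Carlo cross-validation: repeated random train/val resplits.

    The test set stays fixed; each fold draws a fresh stratified train/val
    split of ``bags`` and trains from scratch with a fold-derived seed.
    ``make_estimator(fold_seed)`` must return an unfitted estimator exposing
    ``fit(train_bags, X_val=...)`` and ``predict_proba``. An optional
    ``extra_metrics(estimator, test_bags) -> dict`` callback adds columns
    (e.g. localization scores). Returns one row of test metrics per fold;
    aggregate with ``.mean()`` / ``.std()``.
    """
    rng = np.random.default_rng(seed)
    labels = np.array([b.slide_label for b in bags])
    y_test = [b.slide_label for b in test_bags]
    rows = []
    for fold in range(n_folds):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        frng = np.random.default_rng(fold_seed)
        val_idx: list[int] = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(labels == cls)
            n_val = max(1, int(round(val_fraction * cls_idx.size))) if cls_idx.size else 0
            val_idx.extend(frng.permutation(cls_idx)[:n_val].tolist())
        val_set = set(val_idx)
        train = [b for i, b in enumerate(bags) if i not in val_set]
        val = [b for i, b in enumerate(bags) if i in val_set]
        est = make_estimator(fold_seed)
        est.fit(train, X_val=val)
        p = est.predict_proba(test_bags)[:, 1]
        metrics = classification_metrics(p, y_test)
        if extra_metrics is not None:
            metrics.update(extra_metrics(est, test_bags))
        rows.append({"fold": fold, "seed": fold_seed, **metrics})
    return pd.DataFrame(rows)
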