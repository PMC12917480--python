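"""Scikit-learn style estimator wrapping the rank-induction training loop.

``RankInductionClassifier`` is a bag-level binary classifier: ``X`` is a list
of :class:`~rankmil.bags.Bag` objects (or bare ``(K, D)`` feature matrices
with labels passed as ``y``). Training minimizes

    L = L_BCE(slide) + lambda * L_rank(raw attention scores)

per slide (batch = 1 slide; bags vary in K, so the slide is the natural
optimization unit) with Adam, early-stopping on validation loss after a
warmup period, and restores the best-validation checkpoint. Setting
``rank_weight=0`` recovers the plain attention-MIL baseline (AB-MIL).

The estimator follows scikit-learn conventions — ``get_params``/``set_params``
work, ``clone`` works, fitted attributes end in an underscore — so it composes
with sklearn model selection where bag-list inputs are acceptable.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .bags import Bag
from .losses import RankLossConfig, rank_loss, slide_bce, total_loss
from .model import MILAttentionNet, ModelConfig

__all__ = ["RankInductionClassifier", "EarlyStopper", "AdamOptimizer", "train"]


class EarlyStopper:
    """Patience-based early stopping with a warmup period.

    The monitor is armed at the first epoch after ``warmup``: that epoch's
    loss becomes the baseline, and training stops once ``patience``
    consecutive later epochs fail to improve on the best monitored loss.
    """

    def __init__(self, patience: int = 7, warmup: int = 20):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.warmup = warmup
        self.best: float | None = None
        self.streak = 0

    def should_stop(self, epoch: int, loss: float) -> bool:
        """Feed the epoch's validation loss (1-based epochs); True = stop now."""
        if epoch <= self.warmup:
            return False
        if self.best is None or loss < self.best:
            self.best = loss
            self.streak = 0
        else:
            self.streak += 1
        return self.streak >= self.patience


class AdamOptimizer:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 2e-4, weight_decay: float = 1e-5,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k] + self.wd * p
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            p -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def _as_bags(X, y=None) -> list[Bag]:
    bags = []
    for i, item in enumerate(X):
        if isinstance(item, Bag):
            bags.append(item)
        else:
            label = 0 if y is None else int(y[i])
            bags.append(Bag(slide_id=f"bag_{i}", features=np.asarray(item), slide_label=label))
    return bags


class RankInductionClassifier(BaseEstimator, ClassifierMixin):
    """Attention-MIL slide classifier with rank-induction supervision.

    Parameters
    ----------
    hidden_dim : width of the tanh attention layer.
    gated : use gated (tanh * sigmoid) attention.
    threshold : attention threshold T (cutoff T/K); 0 disables thresholding.
    apply_threshold_at_inference : threshold at predict time too.
    margin, scale : rank-loss margin m and sigmoid scale sigma.
    rank_weight : lambda in L = L_BCE + lambda * L_rank; 0 = AB-MIL baseline.
    max_pos_samples, max_neg_samples : per-slide pair-sampling caps.
    lr, weight_decay : Adam settings.
    max_epochs, patience, warmup_epochs : training schedule; early stopping
        monitors mean validation total loss after the warmup.
    val_fraction : stratified fraction of the training bags held out for
        validation when ``X_val`` is not supplied to :meth:`fit`.
    random_state : seed controlling init, shuffling, pair sampling, splits.

    Attributes
    ----------
    net_ : fitted :class:`~rankmil.model.MILAttentionNet`.
    history_ : per-epoch loss records (train/val components).
    best_epoch_, n_epochs_ : checkpoint epoch and epochs actually run.
    n_features_in_, classes_ : sklearn conventions.
    """

    def __init__(
        self,
        hidden_dim: int = 256,
        gated: bool = False,
        threshold: float = 1.0,
        apply_threshold_at_inference: bool = True,
        margin: float = 1.0,
        scale: float = 1.0,
        rank_weight: float = 1.0,
        max_pos_samples: int = 1024,
        max_neg_samples: int = 1024,
        lr: float = 2e-4,
        weight_decay: float = 1e-5,
        max_epochs: int = 200,
        patience: int = 7,
        warmup_epochs: int = 20,
        val_fraction: float = 0.2,
        random_state: int | None = None,
    ):
        self.hidden_dim = hidden_dim
        self.gated = gated
        self.threshold = threshold
        self.apply_threshold_at_inference = apply_threshold_at_inference
        self.margin = margin
        self.scale = scale
        self.rank_weight = rank_weight
        self.max_pos_samples = max_pos_samples
        self.max_neg_samples = max_neg_samples
        self.lr = lr
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.patience = patience
        self.warmup_epochs = warmup_epochs
        self.val_fraction = val_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------ #
    def _rank_config(self) -> RankLossConfig:
        return RankLossConfig(
            margin=self.margin, scale=self.scale, weight=self.rank_weight,
            max_pos_samples=self.max_pos_samples, max_neg_samples=self.max_neg_samples,
        )

    def _bag_step(self, net, opt, bag: Bag, cfg: RankLossConfig, rng) -> dict:
        cache: dict = {}
        p, _ = net.forward(bag.features, training=True, cache=cache)
        comps = total_loss(bag, p, cache["s"], cfg, rng=None)  # logging only
        dlogit = p - bag.slide_label
        ds_extra = None
        use_rank = (
            cfg.weight > 0 and bag.annotated and bag.patch_labels is not None
            and bool(np.any(bag.patch_labels == 1))
        )
        if use_rank:
            res = rank_loss(cache["s"], bag.patch_labels, cfg, rng=rng, with_grad=True)
            comps["rank"] = res.loss
            comps["pairs_used"] = res.pairs_used
            comps["rank_skipped"] = res.skipped
            comps["total"] = comps["bce"] + cfg.weight * res.loss
            if not res.skipped:
                ds_extra = cfg.weight * res.grad
        grads = net.backward(cache, dlogit, ds_extra=ds_extra)
        if not all(np.all(np.isfinite(g)) for g in grads.values()):
            raise FloatingPointError("non-finite gradient: training diverged")
        opt.step(grads)
        return comps

    # ------------------------------------------------------------------ #
    def fit(self, X, y=None, X_val=None, y_val=None):
        """Fit on a list of bags (or feature matrices + labels).

        ``X_val`` supplies an explicit validation set; otherwise a stratified
        ``val_fraction`` of ``X`` is held out using ``random_state``.
        """
        bags = _as_bags(X, y)
        if len(bags) == 0:
            raise ValueError("empty training set")
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(seed)

        if X_val is not None:
            val_bags = _as_bags(X_val, y_val)
            train_bags = bags
        else:
            labels = np.array([b.slide_label for b in bags])
            val_idx: list[int] = []
            for cls in np.unique(labels):
                cls_idx = np.flatnonzero(labels == cls)
                n_val = int(round(self.val_fraction * cls_idx.size))
                val_idx.extend(rng.permutation(cls_idx)[:n_val].tolist())
            val_set = set(val_idx)
            train_bags = [b for i, b in enumerate(bags) if i not in val_set]
            val_bags = [b for i, b in enumerate(bags) if i in val_set]
        if not train_bags:
            raise ValueError("empty train split")

        D = train_bags[0].n_features
        model_cfg = ModelConfig(
            feature_dim=D, attention_hidden_dim=self.hidden_dim, gated=self.gated,
            threshold=self.threshold,
            apply_threshold_at_inference=self.apply_threshold_at_inference,
        )
        net = MILAttentionNet(model_cfg, seed=seed)
        opt = AdamOptimizer(net.params, lr=self.lr, weight_decay=self.weight_decay)
        cfg = self._rank_config()
        stopper = EarlyStopper(patience=self.patience, warmup=self.warmup_epochs)

        history: list[dict] = []
        best_val = np.inf
        best_params = {k: v.copy() for k, v in net.params.items()}
        best_epoch = 0
        n_epochs = 0
        for epoch in range(1, self.max_epochs + 1):
            n_epochs = epoch
            order = rng.permutation(len(train_bags))
            tr = {"bce": 0.0, "rank": 0.0, "total": 0.0}
            for i in order:
                comps = self._bag_step(net, opt, train_bags[i], cfg, rng)
                for k in tr:
                    tr[k] += comps[k]
            for k in tr:
                tr[k] /= len(train_bags)

            val = {"bce": 0.0, "rank": 0.0, "total": 0.0}
            if val_bags:
                for bag in val_bags:
                    p, state = net.forward(bag.features, training=True)
                    comps = total_loss(bag, p, state.raw_scores, cfg, rng=rng)
                    for k in val:
                        val[k] += comps[k]
                for k in val:
                    val[k] /= len(val_bags)
            monitored = val["total"] if val_bags else tr["total"]
            history.append(
                {"epoch": epoch, "train_bce": tr["bce"], "train_rank": tr["rank"],
                 "train_total": tr["total"], "val_bce": val["bce"], "val_rank": val["rank"],
                 "val_total": val["total"]}
            )
            if monitored < best_val:
                best_val = monitored
                best_params = {k: v.copy() for k, v in net.params.items()}
                best_epoch = epoch
            if stopper.should_stop(epoch, monitored):
                break

        net.params = best_params
        self.net_ = net
        self.history_ = history
        self.best_epoch_ = best_epoch
        self.n_epochs_ = n_epochs
        self.n_features_in_ = D
        self.classes_ = np.array([0, 1])
        return self

    # ------------------------------------------------------------------ #
    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        bags = _as_bags(X)
        probs = np.empty((len(bags), 2))
        for i, bag in enumerate(bags):
            p, _ = self.net_.forward(bag.features, training=False)
            probs[i] = (1.0 - p, p)
        return probs

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def attention(self, bag, use_threshold: bool | None = None):
        """AttentionState for one bag (raw scores, softmax and thresholded weights).

        ``use_threshold`` overrides ``apply_threshold_at_inference`` for this
        call (the thresholded weights fall back to the plain softmax when off).
        """
        self._check_fitted()
        features = bag.features if isinstance(bag, Bag) else np.asarray(bag)
        training = use_threshold if use_threshold is not None else False
        _, state = self.net_.forward(features, training=training)
        return state

    def save(self, path) -> None:
        self._check_fitted()
        self.net_.save(path)


def train(train_bags, val_bags=None, **params) -> RankInductionClassifier:
    """Thin functional wrapper: fit a RankInductionClassifier on bag lists."""
    est = RankInductionClassifier(**params)
    est.fit(train_bags, X_val=val_bags)
    return est
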