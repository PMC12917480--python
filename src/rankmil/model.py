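"""Attention-based MIL network with attention thresholding.

The network scores every patch feature vector z_k with a two-layer tanh
attention head (optionally gated), normalizes the raw scores with a softmax,
optionally zeroes weights below ``T/K`` and renormalizes the survivors, pools
the instance features with the resulting weights, and classifies the pooled
slide embedding with a logistic head:

    s_k = w^T tanh(V z_k + b)                      (raw attention score)
    a_k = softmax(s)_k                             (attention weight)
    a-bar_k = a_k 1[a_k >= T/K] / sum_j a_j 1[...]  (thresholded weight)
    M = sum_k a-bar_k z_k,   p = sigmoid(c^T M + c0)

Thresholding counters representation dilution: in a large bag, thousands of
near-zero weights on normal patches can still out-mass a handful of
high-attention lesion patches in the weighted sum. With T=1 the cutoff is the
uniform weight 1/K, i.e. below-uniform weights are suppressed. If no weight
survives, the argmax patch alone is kept (never an all-zero vector). The
indicator is treated as a constant under differentiation (straight-through):
gradients flow through surviving weights only.

Everything is plain numpy with hand-derived gradients (verified by a
finite-difference check in the test suite); the network is small enough that
no autodiff framework is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

__all__ = [
    "ModelConfig",
    "AttentionState",
    "MILAttentionNet",
    "attention_scores",
    "softmax_weights",
    "threshold_renormalize",
    "pool_and_classify",
]


@dataclass
class ModelConfig:
    """Architecture and thresholding hyperparameters.

    feature_dim: instance feature dimension D (free; common extractors give 2048).
    attention_hidden_dim: width of the tanh attention layer.
    gated: use the gated (tanh * sigmoid) attention variant.
    threshold: attention threshold T >= 0; cutoff is T/K (T times the uniform
        weight). T=0 disables thresholding, T=1 suppresses below-uniform weights.
    apply_threshold_at_inference: keep thresholding on at predict time
        (train/test consistency); set False to threshold during training only.
    """

    feature_dim: int
    attention_hidden_dim: int = 256
    gated: bool = False
    threshold: float = 1.0
    apply_threshold_at_inference: bool = True

    def __post_init__(self) -> None:
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold T must be >= 0")


@dataclass
class AttentionState:
    """Per-bag attention diagnostics: raw scores, softmax weights, thresholded weights."""

    raw_scores: np.ndarray
    softmax_weights: np.ndarray
    thresholded_weights: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        a, abar = self.softmax_weights, self.thresholded_weights
        if abs(a.sum() - 1.0) > 1e-6:
            raise ValueError("softmax weights must sum to 1")
        if (abar < 0).any() or abs(abar.sum() - 1.0) > 1e-6:
            raise ValueError("thresholded weights must be a probability vector")


def softmax_weights(s: np.ndarray) -> np.ndarray:
    """Numerically stabilized softmax (max subtraction)."""
    s = np.asarray(s, dtype=float)
    e = np.exp(s - s.max())
    return e / e.sum()


def threshold_renormalize(a: np.ndarray, T: float) -> np.ndarray:
    """Zero weights below T/K and renormalize the survivors.

    T=0 returns ``a`` unchanged. Boundary is inclusive: a weight exactly at
    T/K survives. If nothing survives, the argmax weight alone is kept
    (lowest index on ties), so the result is always a probability vector.
    """
    if T < 0:
        raise ValueError("threshold T must be >= 0")
    a = np.asarray(a, dtype=float)
    if T == 0:
        return a.copy()
    keep = a >= T / a.size
    if not keep.any():
        out = np.zeros_like(a)
        out[np.argmax(a)] = 1.0
        return out
    out = np.where(keep, a, 0.0)
    return out / out.sum()


def attention_scores(features: np.ndarray, params: dict[str, np.ndarray], gated: bool = False) -> np.ndarray:
    """Raw attention scores s_k = w^T tanh(V z_k + b), optionally gated."""
    features = np.asarray(features, dtype=float)
    t = np.tanh(features @ params["V"].T + params["b"])
    if gated:
        g = expit(features @ params["U"].T + params["c"])
        return (t * g) @ params["w"]
    return t @ params["w"]


def pool_and_classify(features: np.ndarray, weights: np.ndarray, params: dict[str, np.ndarray]) -> float:
    """Attention-weighted pooling M = sum_k w_k z_k, then logistic head."""
    if abs(np.sum(weights) - 1.0) > 1e-6 or (np.asarray(weights) < 0).any():
        raise ValueError("pooling weights must be a probability vector")
    M = weights @ np.asarray(features, dtype=float)
    return float(expit(M @ params["cw"] + params["cb"]))


class MILAttentionNet:
    """The full attention-MIL network: parameters, forward pass, gradients.

    Parameters are held in a flat dict (V, b, w [, U, c], cw, cb) and
    initialized deterministically from a seed. The class is a numerical core;
    the scikit-learn facing estimator lives in :mod:`rankmil.estimator`.
    """

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        D, H = config.feature_dim, config.attention_hidden_dim
        scale_in = 1.0 / np.sqrt(D)
        self.params: dict[str, np.ndarray] = {
            "V": rng.normal(0.0, scale_in, size=(H, D)),
            "b": np.zeros(H),
            "w": rng.normal(0.0, 1.0 / np.sqrt(H), size=H),
            "cw": rng.normal(0.0, scale_in, size=D),
            "cb": np.zeros(()),
        }
        if config.gated:
            self.params["U"] = rng.normal(0.0, scale_in, size=(H, D))
            self.params["c"] = np.zeros(H)

    # ------------------------------------------------------------------ #
    def forward(self, features: np.ndarray, training: bool = True, cache: dict | None = None):
        """Run the bag through the network.

        Returns ``(p, AttentionState)``. Pass a dict as ``cache`` to collect
        the intermediates needed by :meth:`backward`.
        """
        cfg = self.config
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != cfg.feature_dim:
            raise ValueError(
                f"expected features of shape (K, {cfg.feature_dim}), got {features.shape}"
            )
        pre = features @ self.params["V"].T + self.params["b"]
        t = np.tanh(pre)
        if cfg.gated:
            g = expit(features @ self.params["U"].T + self.params["c"])
            h = t * g
        else:
            g = None
            h = t
        s = h @ self.params["w"]
        a = softmax_weights(s)
        T = cfg.threshold if (training or cfg.apply_threshold_at_inference) else 0.0
        abar = threshold_renormalize(a, T)
        M = abar @ features
        logit = float(M @ self.params["cw"] + self.params["cb"])
        p = float(expit(logit))
        state = AttentionState(raw_scores=s, softmax_weights=a, thresholded_weights=abar, threshold=T)
        if cache is not None:
            cache.update(
                features=features, t=t, g=g, h=h, s=s, a=a, abar=abar, M=M,
                logit=logit, p=p, T=T,
            )
        return p, state

    # ------------------------------------------------------------------ #
    def backward(self, cache: dict, dlogit: float, ds_extra: np.ndarray | None = None) -> dict[str, np.ndarray]:
        """Gradients of the per-bag loss w.r.t. all parameters.

        ``dlogit`` is dL/d(classifier logit) (for BCE: p - label).
        ``ds_extra`` is an optional dL/ds contribution applied directly to the
        raw attention scores (the rank loss path, which bypasses the softmax).
        The threshold indicator is straight-through: dL/da is non-zero only on
        surviving weights.
        """
        Z, t, g, h = cache["features"], cache["t"], cache["g"], cache["h"]
        a, abar, T = cache["a"], cache["abar"], cache["T"]
        w, cw = self.params["w"], self.params["cw"]

        grads: dict[str, np.ndarray] = {}
        grads["cw"] = dlogit * cache["M"]
        grads["cb"] = np.asarray(dlogit)

        dM = dlogit * cw                      # (D,)
        dabar = Z @ dM                        # (K,)

        # a-bar = (a * I) / S with the indicator I constant; S = sum(a * I).
        # d(a-bar_k)/d(a_j) = I_j/S * (delta_kj - a-bar_k); T=0 is the identity.
        if T == 0:
            da = dabar
        else:
            keep = abar > 0
            S = float(a[keep].sum())
            da = np.where(keep, (dabar - float(dabar @ abar)) / S, 0.0)

        # softmax backward: ds = a * (da - a . da)
        ds = a * (da - float(a @ da))
        if ds_extra is not None:
            ds = ds + ds_extra

        grads["w"] = h.T @ ds
        if self.config.gated:
            dh = np.outer(ds, w)
            dt = dh * g
            dg = dh * t
            dpre_t = dt * (1.0 - t**2)
            dpre_g = dg * g * (1.0 - g)
            grads["V"] = dpre_t.T @ Z
            grads["b"] = dpre_t.sum(axis=0)
            grads["U"] = dpre_g.T @ Z
            grads["c"] = dpre_g.sum(axis=0)
        else:
            dpre = np.outer(ds, w) * (1.0 - t**2)
            grads["V"] = dpre.T @ Z
            grads["b"] = dpre.sum(axis=0)
        return grads

    # ------------------------------------------------------------------ #
    def save(self, path) -> None:
        """Single-file checkpoint: parameter tree + config echo."""
        np.savez(path, __config__=json.dumps(asdict(self.config)), **self.params)

    @classmethod
    def load(cls, path) -> "MILAttentionNet":
        with np.load(path, allow_pickle=False) as data:
            config = ModelConfig(**json.loads(str(data["__config__"])))
            net = cls(config, seed=0)
            for k in net.params:
                net.params[k] = data[k].copy()
        return net
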