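"""Reference attention-based classifier over tag-count vectors.

The predictor h maps a count vector to the probability of the positive
(AD) class.  Each of the d features becomes a token: a learned per-tag
embedding scaled by the standardized count (plus a per-tag bias), so
self-attention ranges over the features *within* one record and can
model intra-feature relationships.  A stack of multi-head attention
layers is followed by a 1-D convolution along the token axis, mean
pooling, and a 2-way softmax.  Training uses stochastic gradient
descent with momentum, class-weight correction for imbalance (default
7:3), and early stopping on a validation split.

The counterfactual machinery does not privilege this model: anything
exposing scikit-learn's ``predict_proba``/``classes_`` contract can be
explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import (accuracy_score, f1_score, precision_score,
                             recall_score, roc_auc_score)

from ._autodiff import SGD, Adam, Tensor

__all__ = ["ClassifierConfig", "AttentionTagClassifier", "train_classifier"]


@dataclass
class ClassifierConfig:
    """Architecture and training settings for the reference model."""

    embedding_dim: int = 16
    n_layers: int = 6
    n_heads: int = 2
    conv_channels: int = 8
    kernel_size: int = 3
    class_weight_ratio: tuple[float, float] = (7.0, 3.0)  # minority : majority
    optimizer: str = "sgd"
    momentum: float = 0.9
    learning_rate: float = 0.05
    epochs: int = 150
    batch_size: int = 64
    patience: int = 20
    split: tuple[float, float, float] = (0.81, 0.09, 0.10)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.n_layers < 1:
            raise ValueError("need at least one attention layer")
        if any(w <= 0 for w in self.class_weight_ratio):
            raise ValueError("class weights must be positive")
        if self.embedding_dim % self.n_heads:
            raise ValueError("embedding_dim must be divisible by n_heads")


class AttentionTagClassifier(BaseEstimator, ClassifierMixin):
    """Multi-head-attention classifier over per-feature tokens.

    Accepts any feature count d (27 for the tag schema, fewer for
    toys).  Follows scikit-learn estimator conventions; fitted state
    carries trailing underscores.
    """

    def __init__(self, embedding_dim: int = 16, n_layers: int = 6, n_heads: int = 2,
                 conv_channels: int = 8, kernel_size: int = 3,
                 class_weight_ratio: tuple[float, float] = (7.0, 3.0),
                 optimizer: str = "sgd", momentum: float = 0.9,
                 learning_rate: float = 0.05, epochs: int = 150,
                 batch_size: int = 64, patience: int = 20,
                 val_fraction: float = 0.1, seed: int = 0):
        self.embedding_dim = embedding_dim
        self.n_layers = n_layers
        self.n_heads = n_heads
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.class_weight_ratio = class_weight_ratio
        self.optimizer = optimizer
        self.momentum = momentum
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    @classmethod
    def from_config(cls, config: ClassifierConfig) -> "AttentionTagClassifier":
        return cls(
            embedding_dim=config.embedding_dim, n_layers=config.n_layers,
            n_heads=config.n_heads, conv_channels=config.conv_channels,
            kernel_size=config.kernel_size,
            class_weight_ratio=config.class_weight_ratio,
            optimizer=config.optimizer, momentum=config.momentum,
            learning_rate=config.learning_rate, epochs=config.epochs,
            batch_size=config.batch_size, patience=config.patience,
            seed=config.seed,
        )

    # ------------------------------------------------------------------
    def _init_params(self, d: int, rng: np.random.Generator) -> dict[str, Tensor]:
        e, c, ks = self.embedding_dim, self.conv_channels, self.kernel_size
        def t(arr):
            return Tensor(arr, requires_grad=True)
        p = {
            "embed": t(rng.normal(0, 0.5, (d, e))),
            "bias": t(rng.normal(0, 0.1, (d, e))),
            "conv": t(rng.normal(0, 1 / np.sqrt(ks * e), (ks, e, c))),
            "conv_b": t(np.zeros(c)),
            "out_w": t(rng.normal(0, 1 / np.sqrt(c), (c, 2))),
            "out_b": t(np.zeros(2)),
        }
        for layer in range(self.n_layers):
            for name in ("q", "k", "v", "o"):
                p[f"{name}{layer}"] = t(rng.normal(0, 1 / np.sqrt(e), (e, e)))
        return p

    def _forward(self, x_std: np.ndarray, p: dict[str, Tensor]) -> Tensor:
        n, d = x_std.shape
        e, h = self.embedding_dim, self.n_heads
        dk = e // h
        x = Tensor(x_std.reshape(n, d, 1))
        tokens = x * p["embed"] + p["bias"]          # (n, d, e)
        for layer in range(self.n_layers):
            q = tokens @ p[f"q{layer}"]
            k = tokens @ p[f"k{layer}"]
            v = tokens @ p[f"v{layer}"]
            def heads(t_):
                return t_.reshape(n, d, h, dk).transpose(0, 2, 1, 3)  # (n, h, d, dk)
            qh, kh, vh = heads(q), heads(k), heads(v)
            scores = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
            attn = scores.softmax(axis=-1) @ vh       # (n, h, d, dk)
            merged = attn.transpose(0, 2, 1, 3).reshape(n, d, e)
            tokens = tokens + (merged @ p[f"o{layer}"]).tanh()
        # 1-D convolution along the token axis
        ks = self.kernel_size
        d_out = d - ks + 1
        conv = None
        for off in range(ks):
            piece = tokens.slice((slice(None), slice(off, off + d_out), slice(None)))
            term = piece @ p["conv"].slice((off,))    # (n, d_out, c)
            conv = term if conv is None else conv + term
        conv = (conv + p["conv_b"]).relu()
        pooled = conv.mean(axis=1)                    # (n, c)
        return pooled @ p["out_w"] + p["out_b"]       # logits (n, 2)

    @staticmethod
    def _loss(logits: Tensor, y_idx: np.ndarray, weights: np.ndarray) -> Tensor:
        lse = logits.logsumexp(axis=1, keepdims=True)
        logp = logits - lse
        mask = np.zeros(logits.shape)
        mask[np.arange(len(y_idx)), y_idx] = weights
        return -(logp * Tensor(mask)).sum() / float(len(y_idx))

    # ------------------------------------------------------------------
    def fit(self, X, y) -> "AttentionTagClassifier":
        X_arr, index_cols = self._to_array(X, fit=True)
        y_arr = np.asarray(pd.Series(list(y)))
        self.classes_ = np.unique(y_arr)
        if len(self.classes_) != 2:
            raise ValueError("binary labels required (exactly two classes)")
        y_idx = (y_arr == self.classes_[1]).astype(int)

        self.feature_means_ = X_arr.mean(axis=0)
        sd = X_arr.std(axis=0)
        self.feature_scales_ = np.where(sd > 0, sd, 1.0)
        x_std = (X_arr - self.feature_means_) / self.feature_scales_

        counts = np.bincount(y_idx, minlength=2)
        minority = int(np.argmin(counts))
        w_min, w_maj = self.class_weight_ratio
        cw = np.empty(2)
        cw[minority], cw[1 - minority] = w_min, w_maj
        cw *= 2.0 / cw.sum()
        sample_w = cw[y_idx]

        rng = np.random.default_rng(self.seed)
        params = self._init_params(X_arr.shape[1], rng)
        flat = list(params.values())
        if self.optimizer == "sgd":
            opt = SGD(flat, lr=self.learning_rate, momentum=self.momentum)
        elif self.optimizer == "adam":
            opt = Adam(flat, lr=self.learning_rate)
        else:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

        n = len(x_std)
        perm = rng.permutation(n)
        n_val = max(int(round(self.val_fraction * n)), 1) if n > 10 else 0
        val_idx, tr_idx = perm[:n_val], perm[n_val:]

        best_val, best_state, stale = np.inf, None, 0
        self.loss_trace_ = []
        for epoch in range(self.epochs):
            order = rng.permutation(tr_idx)
            epoch_loss = 0.0
            for start in range(0, len(order), self.batch_size):
                take = order[start:start + self.batch_size]
                logits = self._forward(x_std[take], params)
                loss = self._loss(logits, y_idx[take], sample_w[take])
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += loss.item() * len(take)
            self.loss_trace_.append(epoch_loss / max(len(order), 1))
            if n_val:
                logits = self._forward(x_std[val_idx], params)
                val_loss = self._loss(logits, y_idx[val_idx], sample_w[val_idx]).item()
                if val_loss < best_val - 1e-6:
                    best_val, stale = val_loss, 0
                    best_state = {k: t.data.copy() for k, t in params.items()}
                else:
                    stale += 1
                    if stale >= self.patience:
                        break
        if best_state is not None:
            for k_, t_ in params.items():
                t_.data = best_state[k_]
        self.params_ = params
        return self

    def _to_array(self, X, fit: bool = False) -> tuple[np.ndarray, list | None]:
        if isinstance(X, pd.DataFrame):
            if fit:
                self.feature_names_in_ = list(X.columns)
            elif hasattr(self, "feature_names_in_"):
                if list(X.columns) != self.feature_names_in_:
                    if set(X.columns) != set(self.feature_names_in_):
                        raise ValueError("feature columns do not match training schema")
                    X = X[self.feature_names_in_]
            return X.to_numpy(dtype=float), list(X.columns)
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if not fit and arr.shape[1] != len(self.feature_means_):
            raise ValueError(
                f"expected {len(self.feature_means_)} features, got {arr.shape[1]}")
        return arr, None

    def predict_proba(self, X) -> np.ndarray:
        arr, _ = self._to_array(X)
        x_std = (arr - self.feature_means_) / self.feature_scales_
        logits = self._forward(x_std, self.params_).data
        logits -= logits.max(axis=1, keepdims=True)
        expd = np.exp(logits)
        return expd / expd.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    # -- checkpointing --------------------------------------------------
    def save(self, path) -> None:
        import json
        payload = {
            "schema_version": 1,
            "config": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "feature_names": getattr(self, "feature_names_in_", None),
            "feature_means": self.feature_means_.tolist(),
            "feature_scales": self.feature_scales_.tolist(),
            "params": {k: t.data.tolist() for k, t in self.params_.items()},
            "param_shapes": {k: list(t.data.shape) for k, t in self.params_.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "AttentionTagClassifier":
        import json
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("schema_version") != 1:
            raise ValueError("unsupported classifier checkpoint schema")
        cfg = payload["config"]
        cfg["class_weight_ratio"] = tuple(cfg["class_weight_ratio"])
        model = cls(**cfg)
        model.classes_ = np.asarray(payload["classes"])
        if payload["feature_names"]:
            model.feature_names_in_ = payload["feature_names"]
        model.feature_means_ = np.asarray(payload["feature_means"], dtype=float)
        model.feature_scales_ = np.asarray(payload["feature_scales"], dtype=float)
        model.params_ = {
            k: Tensor(np.asarray(v, dtype=float).reshape(payload["param_shapes"][k]),
                      requires_grad=True)
            for k, v in payload["params"].items()
        }
        return model


def train_classifier(X, y, config: ClassifierConfig | None = None):
    """Train the reference model with a held-out evaluation split.

    Splits the data into train/validation/test fractions (default
    81/9/10), fits with early stopping on the validation part, and
    reports accuracy, precision, recall, F1 and AUC on the test part.

    Returns (model, metrics dict).
    """
    config = config or ClassifierConfig()
    y_arr = np.asarray(pd.Series(list(y)))
    classes = np.unique(y_arr)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)

    rng = np.random.default_rng(config.seed)
    n = len(X_arr)
    perm = rng.permutation(n)
    n_train = int(round(config.split[0] * n))
    n_val = int(round(config.split[1] * n))
    tr, va, te = perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]

    model = AttentionTagClassifier.from_config(config)
    # hand the validation part to the estimator's early stopping
    fit_idx = np.concatenate([va, tr])
    model.val_fraction = len(va) / len(fit_idx) if len(fit_idx) else 0.0
    model.fit(X_arr[fit_idx], y_arr[fit_idx])

    pos = model.classes_[1]
    y_true = y_arr[te]
    proba = model.predict_proba(X_arr[te])[:, 1]
    y_pred = model.classes_[(proba > 0.5).astype(int)]
    metrics = {
        "accuracy": accuracy_score(y_true, y_pred),
        "precision": precision_score(y_true, y_pred, pos_label=pos, zero_division=0),
        "recall": recall_score(y_true, y_pred, pos_label=pos, zero_division=0),
        "f1": f1_score(y_true, y_pred, pos_label=pos, zero_division=0),
        "auc": roc_auc_score((y_true == pos).astype(int), proba),
        "n_test": int(len(te)),
    }
    return model, metrics
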