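"""Per-strategy image classifiers and the tabular metadata baseline.

The audit's logic is backbone-agnostic: any model exposing per-class
probabilities and a penultimate-layer embedding can be plugged in behind
:class:`ModelHandle`.  The built-in backbone is a deliberately compact one —
a multilayer perceptron over block-mean-pooled pixels — so that a full
5-strategy x 5-fold audit runs in minutes on one CPU while still learning
blob-like disease signals, bright device tokens, border text and
ROI-size cues.  It follows the full-scale training protocol: multi-label
sigmoid outputs, (optionally class-weighted) cross-entropy, Adam, and early
stopping on a held-out fold's validation loss.

Training-time augmentation (horizontal flip, brightness, rotation) operates
on the already-masked images; rotation therefore rotates the masked-out
hole, so the desk-scale protocol keeps it off by default and relies on the
masking-commuting augmentations only.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as nd_rotate
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "ModelHandle",
    "PooledMLPClassifier",
    "make_folds",
    "train_image_classifier",
    "predict_proba",
    "extract_embeddings",
    "train_tabular_baseline",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol.

    Defaults mirror the full-scale protocol (lr 1e-4, batch 32, 250 epochs,
    early stopping after 10 epochs without a validation-loss improvement of
    1e-3, rotation +/-45 deg, horizontal flip p=0.5, brightness 0.7-1.1).
    :meth:`desk_scale` returns the reduced protocol used for synthetic
    desk-scale runs.
    """

    learning_rate: float = 1e-4
    batch_size: int = 32
    loss: str = "cross_entropy"  # or "weighted_cross_entropy"
    max_epochs: int = 250
    early_stop_patience: int = 10
    early_stop_delta: float = 1e-3
    rotation_deg: float = 45.0
    hflip_prob: float = 0.5
    brightness_range: tuple[float, float] = (0.7, 1.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if not self.brightness_range[0] < self.brightness_range[1]:
            if self.brightness_range[0] != self.brightness_range[1]:
                raise ValueError("brightness_range must satisfy low < high")
        if self.loss not in ("cross_entropy", "weighted_cross_entropy"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @classmethod
    def desk_scale(cls, seed: int = 0, **overrides) -> "TrainingConfig":
        """Protocol for small synthetic runs: higher learning rate for the
        compact backbone, rotation and brightness jitter off (they do not
        commute with masking), horizontal flip kept."""
        params = dict(
            learning_rate=1e-3,
            batch_size=32,
            loss="cross_entropy",
            max_epochs=120,
            early_stop_patience=10,
            early_stop_delta=1e-3,
            rotation_deg=0.0,
            hflip_prob=0.5,
            brightness_range=(1.0, 1.0),
            seed=seed,
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class ModelHandle:
    """Opaque reference to a trained model plus its audit-relevant metadata."""

    model: "PooledMLPClassifier"
    embedding_dim: int
    class_names: list[str]
    strategy: str = "FULL"
    fold: int = 0

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(images)

    def embed(self, images: np.ndarray) -> np.ndarray:
        return self.model.embed(images)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class PooledMLPClassifier(BaseEstimator, ClassifierMixin):
    """Compact multi-label image classifier: block-mean pooling -> one hidden
    ReLU layer -> independent sigmoid outputs per class.

    The penultimate (hidden) activations are the model's embedding, exposed
    via :meth:`embed`; applying the stored linear head to the embedding
    reproduces :meth:`predict_proba` exactly.

    Parameters
    ----------
    pool_size : side length of the pooled working grid (input images are
        block-mean pooled to ``pool_size x pool_size`` features).
    hidden_dim : embedding dimension of the hidden layer.
    learning_rate, batch_size, loss, max_epochs, early_stop_patience,
    early_stop_delta, rotation_deg, hflip_prob, brightness_range :
        see :class:`TrainingConfig`.
    validation_fraction : fraction split off for early stopping when no
        explicit validation set is passed to :meth:`fit`.
    random_state : seed for weight init, batching and augmentation.
    """

    def __init__(
        self,
        pool_size: int = 32,
        hidden_dim: int = 64,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        loss: str = "cross_entropy",
        max_epochs: int = 120,
        early_stop_patience: int = 10,
        early_stop_delta: float = 1e-3,
        rotation_deg: float = 0.0,
        hflip_prob: float = 0.5,
        brightness_range: tuple[float, float] = (1.0, 1.0),
        validation_fraction: float = 0.15,
        min_feature_support: float = 0.05,
        random_state: int = 0,
    ):
        self.pool_size = pool_size
        self.hidden_dim = hidden_dim
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.loss = loss
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.early_stop_delta = early_stop_delta
        self.rotation_deg = rotation_deg
        self.hflip_prob = hflip_prob
        self.brightness_range = brightness_range
        self.validation_fraction = validation_fraction
        self.min_feature_support = min_feature_support
        self.random_state = random_state

    # -- features ----------------------------------------------------------

    def _check_images(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            X = X[None]
        if X.ndim != 3:
            raise ValueError(f"expected images of shape (n, H, W), got {X.shape}")
        if hasattr(self, "input_shape_") and X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"images of shape {X.shape[1:]} do not match the fitted size {self.input_shape_}"
            )
        if not np.isfinite(X).all():
            raise ValueError("images contain non-finite values")
        return X

    def _pool(self, X: np.ndarray) -> np.ndarray:
        """Block-mean and block-max pooled pixels, concatenated.

        The mean channel carries diffuse intensity structure (blobs, ROI
        area); the max channel makes small high-contrast marks (device
        tokens, glyphs) detectable regardless of where they fall within a
        block, emulating a convolutional detector's translation tolerance.
        """
        n, h, w = X.shape
        p = self.pool_size
        if h < p or w < p:
            raise ValueError(f"images ({h}x{w}) smaller than pool_size {p}")
        # crop to a multiple of the pooled grid, then pool per block
        bh, bw = h // p, w // p
        Xb = X[:, : bh * p, : bw * p].reshape(n, p, bh, p, bw)
        return np.concatenate(
            [Xb.mean(axis=(2, 4)).reshape(n, p * p), Xb.max(axis=(2, 4)).reshape(n, p * p)],
            axis=1,
        )

    def _features(self, X: np.ndarray) -> np.ndarray:
        F = self._pool(X)
        z = (F - self.feat_mean_) / self.feat_scale_
        # clip to the training range: occluded or re-revealed regions push
        # features far outside anything seen in training, and the response
        # of the network out there is unconstrained noise
        return self.feat_active_ * np.clip(z, self.feat_lo_, self.feat_hi_)

    # -- training ----------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        X_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> "PooledMLPClassifier":
        X = self._check_images(X)
        y = np.asarray(y)
        if y.ndim == 1:
            y = y[:, None]
        y = y.astype(np.float64)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        for c in range(y.shape[1]):
            if len(np.unique(y[:, c])) < 2:
                raise ValueError(f"training labels for class {c} contain a single class")
        rng = np.random.default_rng(self.random_state)
        self.input_shape_ = X.shape[1:]
        self.classes_ = np.array([0, 1])
        self.n_classes_ = y.shape[1]
        self.embedding_dim_ = self.hidden_dim

        if X_val is None:
            n = X.shape[0]
            n_val = max(1, int(round(self.validation_fraction * n)))
            perm = rng.permutation(n)
            val_idx, tr_idx = perm[:n_val], perm[n_val:]
            X, X_val, y, y_val = X[tr_idx], X[val_idx], y[tr_idx], y[val_idx]
        else:
            X_val = self._check_images(X_val)
            y_val = np.asarray(y_val, dtype=np.float64)
            if y_val.ndim == 1:
                y_val = y_val[:, None]

        # feature standardization on the (un-augmented) training pool
        F = self._pool(X)
        self.feat_mean_ = F.mean(axis=0)
        self.feat_scale_ = F.std(axis=0)
        # support pruning: the model cannot have learned anything about a
        # feature that never varied in training (pixels always masked out) or
        # was visible in only a handful of images, so such features are
        # forced to 0 at inference as well — otherwise near-init weights
        # would inject noise when a masked region reappears (dilation
        # sweeps, cross-masking evaluation).
        support = (F > 0).mean(axis=0)
        self.feat_active_ = (
            (self.feat_scale_ >= 1e-8) & (support >= self.min_feature_support)
        ).astype(np.float64)
        self.feat_scale_[self.feat_scale_ < 1e-8] = 1.0
        z = (F - self.feat_mean_) / self.feat_scale_
        self.feat_lo_ = z.min(axis=0)
        self.feat_hi_ = z.max(axis=0)

        if self.loss == "weighted_cross_entropy":
            n_pos = y.sum(axis=0)
            n_neg = y.shape[0] - n_pos
            self.pos_weight_ = np.where(n_pos > 0, n_neg / np.maximum(n_pos, 1), 1.0)
        else:
            self.pos_weight_ = np.ones(self.n_classes_)

        d_in, d_h, d_out = 2 * self.pool_size**2, self.hidden_dim, self.n_classes_
        W1 = rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, d_h))
        b1 = np.zeros(d_h)
        W2 = rng.normal(0, np.sqrt(2.0 / d_h), size=(d_h, d_out))
        b2 = np.zeros(d_out)
        params = [W1, b1, W2, b2]
        m_adam = [np.zeros_like(p) for p in params]
        v_adam = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0

        def forward(feats):
            h = np.maximum(feats @ params[0] + params[1], 0.0)
            return h, _sigmoid(h @ params[2] + params[3])

        def val_loss():
            _, p = forward(self._features(X_val))
            return float(self._bce(p, y_val))

        augment = self.rotation_deg > 0 or self.hflip_prob > 0 or (
            self.brightness_range[0] != self.brightness_range[1]
        )
        Fs_clean = self._features(X)

        best_loss = np.inf
        best_params = [p.copy() for p in params]
        best_epoch = -1
        wait = 0
        history: list[float] = []
        n_tr = X.shape[0]
        for epoch in range(self.max_epochs):
            if augment:
                Fs = self._features(self._augment(X, rng))
            else:
                Fs = Fs_clean
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, self.batch_size):
                idx = order[start : start + self.batch_size]
                fb, yb = Fs[idx], y[idx]
                h = np.maximum(fb @ params[0] + params[1], 0.0)
                p = _sigmoid(h @ params[2] + params[3])
                # gradient of the (weighted) mean BCE
                w = np.where(yb == 1, self.pos_weight_, 1.0)
                dz2 = w * (p - yb) / (yb.shape[0] * self.n_classes_)
                gW2 = h.T @ dz2
                gb2 = dz2.sum(axis=0)
                dh = dz2 @ params[2].T
                dh[h <= 0] = 0.0
                gW1 = fb.T @ dh
                gb1 = dh.sum(axis=0)
                t += 1
                for p_i, g in zip(range(4), (gW1, gb1, gW2, gb2)):
                    m_adam[p_i] = beta1 * m_adam[p_i] + (1 - beta1) * g
                    v_adam[p_i] = beta2 * v_adam[p_i] + (1 - beta2) * g * g
                    mhat = m_adam[p_i] / (1 - beta1**t)
                    vhat = v_adam[p_i] / (1 - beta2**t)
                    params[p_i] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            vl = val_loss()
            history.append(vl)
            if best_loss - vl > self.early_stop_delta:
                best_loss = vl
                best_params = [p.copy() for p in params]
                best_epoch = epoch
                wait = 0
            else:
                wait += 1
                if wait >= self.early_stop_patience:
                    break
        params = best_params
        self.W1_, self.b1_, self.W2_, self.b2_ = params
        self.best_epoch_ = best_epoch
        self.best_val_loss_ = best_loss
        self.val_loss_history_ = history
        self.n_epochs_ = len(history)
        return self

    def _augment(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = X.copy()
        n = out.shape[0]
        if self.hflip_prob > 0:
            flip = rng.random(n) < self.hflip_prob
            out[flip] = out[flip, :, ::-1]
        lo, hi = self.brightness_range
        if lo != hi:
            out *= rng.uniform(lo, hi, size=(n, 1, 1))
        if self.rotation_deg > 0:
            angles = rng.uniform(-self.rotation_deg, self.rotation_deg, size=n)
            for i in range(n):
                out[i] = nd_rotate(out[i], angles[i], reshape=False, order=1, cval=0.0)
        return np.clip(out, 0.0, None)

    def _bce(self, p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, 1e-12, 1 - 1e-12)
        w = np.where(y == 1, self.pos_weight_, 1.0)
        return float(-np.mean(w * (y * np.log(p) + (1 - y) * np.log(1 - p))))

    # -- inference ---------------------------------------------------------

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Penultimate-layer (hidden) activations, shape (n, embedding_dim)."""
        X = self._check_images(X)
        return np.maximum(self._features(X) @ self.W1_ + self.b1_, 0.0)

    def head(self, embeddings: np.ndarray) -> np.ndarray:
        """Apply the stored classification head to embeddings."""
        return _sigmoid(np.asarray(embeddings) @ self.W2_ + self.b2_)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Independent per-class probabilities, shape (n, n_classes)."""
        return self.head(self.embed(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# folds


def make_folds(labels: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Label-stratified fold assignment 0..k-1, deterministic given ``seed``.

    Multi-label vectors stratify on the joint label tuple.  A stratum with
    fewer members than ``k`` degrades to unstratified assignment for those
    records, with a warning.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if labels.shape[0] < k:
        raise ValueError("need at least k records")
    if labels.ndim == 1:
        labels = labels[:, None]
    keys = np.array(["|".join(map(str, row)) for row in labels])
    rng = np.random.default_rng(seed)
    folds = np.empty(labels.shape[0], dtype=int)
    leftover: list[np.ndarray] = []
    offset = 0
    for key in np.unique(keys):
        idx = rng.permutation(np.flatnonzero(keys == key))
        if idx.size < k:
            warnings.warn(
                f"label stratum {key!r} has {idx.size} < {k} records; "
                "assigning it unstratified"
            )
            leftover.append(idx)
            continue
        folds[idx] = (np.arange(idx.size) + offset) % k
        offset += idx.size
    if leftover:
        idx = rng.permutation(np.concatenate(leftover))
        folds[idx] = np.arange(idx.size) % k
    return folds


# ---------------------------------------------------------------------------
# training entry points


def train_image_classifier(
    images: np.ndarray,
    labels: np.ndarray,
    folds: np.ndarray,
    fold: int,
    config: TrainingConfig | None = None,
    strategy: str = "FULL",
    class_names: Sequence[str] | None = None,
    **estimator_kwargs,
) -> ModelHandle:
    """Train one fold model on already-masked images.

    Records in ``fold`` are held out as the validation set for early
    stopping; the rest train.  Returns a :class:`ModelHandle` with embedding
    access.
    """
    config = config or TrainingConfig.desk_scale()
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    folds = np.asarray(folds)
    tr = folds != fold
    va = folds == fold
    est = PooledMLPClassifier(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        loss=config.loss,
        max_epochs=config.max_epochs,
        early_stop_patience=config.early_stop_patience,
        early_stop_delta=config.early_stop_delta,
        rotation_deg=config.rotation_deg,
        hflip_prob=config.hflip_prob,
        brightness_range=config.brightness_range,
        random_state=config.seed + 1000 * fold,
        **estimator_kwargs,
    )
    est.fit(images[tr], labels[tr], X_val=images[va], y_val=labels[va])
    names = list(class_names) if class_names is not None else [
        f"class_{c}" for c in range(labels.shape[1])
    ]
    return ModelHandle(
        model=est,
        embedding_dim=est.embedding_dim_,
        class_names=names,
        strategy=str(strategy),
        fold=int(fold),
    )


def predict_proba(model: ModelHandle, images: np.ndarray) -> np.ndarray:
    """Per-class probabilities in [0, 1], shape (n_images, n_classes)."""
    return model.predict_proba(np.asarray(images))


def extract_embeddings(model: ModelHandle, images: np.ndarray) -> np.ndarray:
    """Penultimate pooled representation, shape (n_images, embedding_dim)."""
    return model.embed(np.asarray(images))


def train_tabular_baseline(
    metadata: pd.DataFrame,
    labels: np.ndarray,
    folds: np.ndarray,
) -> tuple[list, np.ndarray]:
    """Logistic-regression baseline on (sex, birth_year, projection).

    Rows with any missing feature are dropped first.  One model per fold is
    trained on the other folds and scored on its held-out fold with the same
    fold assignment as the image models.  Returns the per-fold fitted
    pipelines and the per-class mean cross-validated AUC.
    """
    from .evaluation import auc as _auc

    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[:, None]
    folds = np.asarray(folds)
    cols = ["sex", "birth_year", "projection"]
    meta = metadata[cols].copy()
    complete = meta.notna().all(axis=1).to_numpy()
    if not complete.any():
        raise ValueError("all rows dropped: every record has a missing feature")
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("tabular baseline: dropped %d rows with missing features", n_dropped)
    meta, labels, folds = meta[complete], labels[complete], folds[complete]
    X = np.column_stack(
        [
            meta["sex"].astype(float).to_numpy(),
            meta["birth_year"].astype(float).to_numpy(),
            (meta["projection"].astype(str) == "PA").astype(float).to_numpy(),
        ]
    )
    models = []
    aucs = np.zeros((len(np.unique(folds)), labels.shape[1]))
    for i, fold in enumerate(np.unique(folds)):
        tr, va = folds != fold, folds == fold
        fold_models = []
        for c in range(labels.shape[1]):
            pipe = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
            pipe.fit(X[tr], labels[tr, c])
            scores = pipe.predict_proba(X[va])[:, 1]
            aucs[i, c] = _auc(scores, labels[va, c])
            fold_models.append(pipe)
        models.append(fold_models)
    return models, aucs.mean(axis=0)


# ---------------------------------------------------------------------------
# persistence


def save_model(handle: ModelHandle, out_dir: str | Path, config: TrainingConfig | None = None) -> Path:
    """Save weights (.npz) plus a JSON sidecar with audit metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"model_{handle.strategy}_fold{handle.fold}"
    est = handle.model
    np.savez(
        out_dir / f"{stem}.npz",
        W1=est.W1_, b1=est.b1_, W2=est.W2_, b2=est.b2_,
        feat_mean=est.feat_mean_, feat_scale=est.feat_scale_,
        feat_active=est.feat_active_,
        feat_lo=est.feat_lo_, feat_hi=est.feat_hi_,
        pos_weight=est.pos_weight_,
        input_shape=np.array(est.input_shape_),
    )
    sidecar = {
        "strategy": handle.strategy,
        "fold": handle.fold,
        "class_names": handle.class_names,
        "embedding_dim": handle.embedding_dim,
        "pool_size": est.pool_size,
        "hidden_dim": est.hidden_dim,
        "best_epoch": est.best_epoch_,
        "n_epochs": est.n_epochs_,
        "config": asdict(config) if config else None,
    }
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir / f"{stem}.npz"


def load_model(npz_path: str | Path) -> ModelHandle:
    npz_path = Path(npz_path)
    sidecar = json.loads(npz_path.with_suffix(".json").read_text())
    data = np.load(npz_path)
    est = PooledMLPClassifier(pool_size=sidecar["pool_size"], hidden_dim=sidecar["hidden_dim"])
    est.W1_, est.b1_ = data["W1"], data["b1"]
    est.W2_, est.b2_ = data["W2"], data["b2"]
    est.feat_mean_, est.feat_scale_ = data["feat_mean"], data["feat_scale"]
    est.feat_active_ = data["feat_active"]
    est.feat_lo_, est.feat_hi_ = data["feat_lo"], data["feat_hi"]
    est.pos_weight_ = data["pos_weight"]
    est.input_shape_ = tuple(int(v) for v in data["input_shape"])
    est.n_classes_ = est.W2_.shape[1]
    est.embedding_dim_ = est.W1_.shape[1]
    est.classes_ = np.array([0, 1])
    return ModelHandle(
        model=est,
        embedding_dim=sidecar["embedding_dim"],
        class_names=sidecar["class_names"],
        strategy=sidecar["strategy"],
        fold=sidecar["fold"],
    )
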