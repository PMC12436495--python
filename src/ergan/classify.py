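"""Transformer classifiers for case/control discrimination.

Two families mirror the study design:

* ``TST`` — an encoder-only time-series transformer that consumes the raw
  235-sample waveform with sinusoidal positional encodings, trained with
  class-weighted cross-entropy, Adam (initial lr 1e-4) and early stopping
  on validation loss with batch size 32.
* ``ViT`` — a vision transformer over 3 x 224 x 224 scalogram images:
  flattened patches, linear patch embedding, a learnable class token with
  positional embeddings, and an encoder of alternating multi-head
  self-attention and MLP blocks, trained with SGD (initial lr 1e-3).

The default configurations are small from-scratch models sized for CPU
training; an externally pretrained hybrid backbone can be named but its
weight file must exist — there is no silent fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autodiff as ad
from .nn.layers import (
    Linear,
    Module,
    TransformerEncoderLayer,
    sinusoidal_positions,
)
from .nn.optim import SGD, Adam


@dataclass(frozen=True)
class TSTConfig:
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 128
    dropout: float = 0.1
    pool: int = 1  # average-pool factor on the input series (1 = none)
    class_weights: bool = True
    lr: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10  # evaluations without val-loss improvement

    def __post_init__(self):
        if self.d_model % self.n_heads:
            raise ValueError(
                f"d_model={self.d_model} must be divisible by n_heads={self.n_heads}"
            )
        if self.pool < 1:
            raise ValueError("pool factor must be >= 1")


#: Externally pretrained hybrid ResNet-ViT backbones the config can name
#: (weight files must be supplied; nothing is downloaded or bundled).
PRETRAINED_BACKBONES = ("ViT_small_r26_s32_224", "ViT_tiny_r_s16_p8_224")


@dataclass(frozen=True)
class ViTConfig:
    side: int = 224
    patch: int = 16
    width: int = 128
    depth: int = 4
    n_heads: int = 4
    d_ff: int = 256
    dropout: float = 0.1
    class_weights: bool = True
    pretrained: str | None = None  # e.g. "ViT_small_r26_s32_224"; needs a weight file
    pretrained_path: str | None = None
    readout: str = "cls"  # "cls" token or "mean" over all tokens
    lr: float = 1e-3
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 60
    patience: int = 10

    def __post_init__(self):
        if self.side % self.patch:
            raise ValueError(f"side {self.side} not divisible by patch {self.patch}")
        if self.readout not in ("cls", "mean"):
            raise ValueError(f"readout must be 'cls' or 'mean', got {self.readout!r}")

    @property
    def n_patches(self) -> int:
        return (self.side // self.patch) ** 2


class TST(Module):
    """Encoder-only transformer on raw waveform sequences."""

    def __init__(self, cfg: TSTConfig, seq_len: int, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.n_tokens = seq_len // cfg.pool
        self.embed = Linear(1, cfg.d_model, rng)
        self.pos = sinusoidal_positions(self.n_tokens, cfg.d_model)[None]  # fixed
        self.blocks = [
            TransformerEncoderLayer(cfg.d_model, cfg.n_heads, cfg.d_ff, rng, cfg.dropout)
            for _ in range(cfg.n_layers)
        ]
        self.head = Linear(cfg.d_model, 2, rng)

    def __call__(self, x: np.ndarray) -> ad.Tensor:
        if self.cfg.pool > 1:  # non-overlapping average pooling on the input
            k, n = self.cfg.pool, self.n_tokens
            x = x[:, : n * k].reshape(x.shape[0], n, k).mean(axis=2)
        h = self.embed(ad.Tensor(x[:, :, None])) + self.pos
        for blk in self.blocks:
            h = blk(h)
        return self.head(h.mean(axis=1))


class ViT(Module):
    """Patch-embedding vision transformer with a learnable class token."""

    def __init__(self, cfg: ViTConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        patch_dim = 3 * cfg.patch * cfg.patch
        self.patch_embed = Linear(patch_dim, cfg.width, rng)
        self.cls_token = ad.Tensor(
            rng.normal(0.0, 0.02, size=(1, 1, cfg.width)), requires_grad=True
        )
        self.pos_embed = ad.Tensor(
            rng.normal(0.0, 0.02, size=(1, cfg.n_patches + 1, cfg.width)),
            requires_grad=True,
        )
        self.blocks = [
            TransformerEncoderLayer(cfg.width, cfg.n_heads, cfg.d_ff, rng, cfg.dropout)
            for _ in range(cfg.depth)
        ]
        self.head = Linear(cfg.width, 2, rng)

    def patchify(self, imgs: np.ndarray) -> np.ndarray:
        """(B, 3, S, S) -> (B, n_patches, 3*p*p) flattened raster-order patches."""
        B, C, S, _ = imgs.shape
        p = self.cfg.patch
        g = S // p
        x = imgs.reshape(B, C, g, p, g, p)
        x = x.transpose(0, 2, 4, 1, 3, 5)  # B, gy, gx, C, p, p
        return x.reshape(B, g * g, C * p * p)

    def __call__(self, imgs: np.ndarray) -> ad.Tensor:
        if imgs.ndim != 4 or imgs.shape[1] != 3 or imgs.shape[2] != self.cfg.side:
            raise ValueError(
                f"expected (B, 3, {self.cfg.side}, {self.cfg.side}) input, got {imgs.shape}"
            )
        B = imgs.shape[0]
        tokens = self.patch_embed(ad.Tensor(self.patchify(imgs)))  # (B, N, W)
        cls = self.cls_token + ad.Tensor(np.zeros((B, 1, self.cfg.width)))
        h = ad.concat([cls, tokens], axis=1) + self.pos_embed
        for blk in self.blocks:
            h = blk(h)
        if self.cfg.readout == "mean":  # global average pooling over tokens
            return self.head(h.mean(axis=1))
        return self.head(h[:, 0, :])


# -- shared training loop -----------------------------------------------------

def class_weight_vector(y: np.ndarray, enabled: bool = True) -> np.ndarray:
    """Inverse-frequency class weights normalised to mean 1 over classes."""
    if not enabled:
        return np.ones(2)
    counts = np.bincount(y, minlength=2).astype(float)
    if np.any(counts == 0):
        raise ValueError("both classes must be present in the training set")
    w = counts.sum() / (2.0 * counts)
    return w / w.mean()


def _weighted_ce(logits: ad.Tensor, y: np.ndarray, weights: np.ndarray) -> ad.Tensor:
    m = logits.data.max(axis=1, keepdims=True)
    shifted = logits - m
    lse = ad.log(ad.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - lse
    onehot = np.zeros_like(logits.data)
    onehot[np.arange(len(y)), y] = 1.0
    w = weights[y]
    picked = (logp * onehot).sum(axis=1)
    return -(picked * w).sum() * (1.0 / w.sum())


def _evaluate_loss(model, X, y, weights, batch: int = 64) -> float:
    model.eval()
    total, wsum = 0.0, 0.0
    for s in range(0, len(y), batch):
        logits = model(X[s : s + batch])
        w = weights[y[s : s + batch]]
        loss = _weighted_ce(logits, y[s : s + batch], weights)
        total += float(loss.data) * w.sum()
        wsum += w.sum()
    model.train()
    return total / wsum


def _fit(model, optimizer, X, y, X_val, y_val, cfg, rng) -> dict:
    """Mini-batch training with early stopping on validation loss."""
    weights = class_weight_vector(y, cfg.class_weights)
    best_loss, best_state, since_best = np.inf, None, 0
    history = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(y))
        for s in range(0, len(y), cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            logits = model(X[idx])
            loss = _weighted_ce(logits, y[idx], weights)
            model.zero_grad()
            loss.backward()
            optimizer.step()
        val_loss = _evaluate_loss(model, X_val, y_val, weights)
        history.append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss, since_best = val_loss, 0
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        model.load_state_dict(best_state)
    return {"val_loss_history": history, "best_val_loss": float(best_loss),
            "epochs_run": len(history)}


def train_tst(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    cfg: TSTConfig = TSTConfig(),
    seed: int = 0,
) -> TST:
    """Train a time-series transformer on raw (normalised) waveforms."""
    y_train = np.asarray(y_train, dtype=int)
    if len(set(y_train)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(seed)
    model = TST(cfg, seq_len=X_train.shape[1], rng=rng)
    opt = Adam(model.parameters(), lr=cfg.lr)
    model.fit_info = _fit(model, opt, X_train, y_train, X_val,
                          np.asarray(y_val, dtype=int), cfg, rng)
    return model


def train_vit(
    imgs_train: np.ndarray,
    y_train: np.ndarray,
    imgs_val: np.ndarray,
    y_val: np.ndarray,
    cfg: ViTConfig = ViTConfig(),
    seed: int = 0,
) -> ViT:
    """Train a ViT on (n, 3, side, side) scalogram images."""
    y_train = np.asarray(y_train, dtype=int)
    if len(set(y_train)) < 2:
        raise ValueError("training set contains a single class")
    rng = np.random.default_rng(seed)
    model = ViT(cfg, rng=rng)
    if cfg.pretrained is not None:
        import os

        if cfg.pretrained_path is None or not os.path.exists(cfg.pretrained_path):
            raise FileNotFoundError(
                f"pretrained backbone {cfg.pretrained!r} requested but no weight "
                f"file found at {cfg.pretrained_path!r}"
            )
        model.load_state_dict(dict(np.load(cfg.pretrained_path)))
    opt = SGD(model.parameters(), lr=cfg.lr, momentum=cfg.momentum)
    model.fit_info = _fit(model, opt, imgs_train, y_train, imgs_val,
                          np.asarray(y_val, dtype=int), cfg, rng)
    return model


def predict(model: Module, X: np.ndarray, batch: int = 64) -> dict[str, np.ndarray]:
    """Class-1 probabilities and 0.5-threshold labels, batch-order invariant."""
    model.eval()
    probs = []
    for s in range(0, len(X), batch):
        logits = model(X[s : s + batch]).data
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        probs.append(p[:, 1])
    model.train()
    p1 = np.concatenate(probs) if probs else np.zeros(0)
    return {"prob": p1, "label": (p1 >= 0.5).astype(int)}
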