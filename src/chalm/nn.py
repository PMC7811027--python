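"""A compact convolutional regression network for read-image arrays.

The encoder output (n_rows x n_cols x 2) is regressed onto expression with
three stacked 2-D convolutions of kernel sizes (5,1), (4,1), (3,1) and
stride (1,1) — kernels span pseudo-reads, not CpG columns, so the network
reads vertical clonal structure — each followed by a rectified-linear
activation, then dropout (p = 0.2) and a single linear output unit.  No
pooling (the column dimension is already small).  Training minimises mean
squared error with the Adam optimizer in batches of 32 regions, with an
internal validation split for early stopping.  Everything is plain numpy
and fully deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .readimage import ReadImage

__all__ = ["ModelConfig", "PredictionResult", "ConvRegressor", "train_and_predict"]


@dataclass(frozen=True)
class ModelConfig:
    kernel_heights: tuple[int, ...] = (5, 4, 3)
    channels: tuple[int, ...] = (8, 8, 4)
    dropout_p: float = 0.2
    batch_size: int = 32
    learning_rate: float = 1e-3
    epochs: int = 50
    patience: int = 5
    train_fraction: float = 0.5
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if len(self.kernel_heights) != len(self.channels):
            raise ValueError("one channel count per conv layer")


@dataclass
class PredictionResult:
    """Held-out predictions from a 50/50 train/test split."""

    test_indices: np.ndarray
    predictions: np.ndarray
    test_targets: np.ndarray
    train_indices: np.ndarray
    epochs_run: int


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    # x: (N, Ci, H, W); w: (Co, Ci, K) height-only kernels
    windows = sliding_window_view(x, w.shape[2], axis=2)  # (N,Ci,H',W,K)
    out = np.einsum("nchwk,ock->nohw", windows, w, optimize=True)
    out += b[np.newaxis, :, np.newaxis, np.newaxis]
    return out, windows


def _conv_backward(dout, windows, x_shape, w):
    dw = np.einsum("nchwk,nohw->ock", windows, dout, optimize=True)
    db = dout.sum(axis=(0, 2, 3))
    dx = np.zeros(x_shape)
    h_out = dout.shape[2]
    for k in range(w.shape[2]):
        dx[:, :, k : k + h_out, :] += np.einsum(
            "nohw,oc->nchw", dout, w[:, :, k], optimize=True
        )
    return dx, dw, db


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class ConvRegressor:
    """Three height-only conv layers + ReLU, dropout, linear head."""

    def __init__(
        self,
        input_shape: tuple[int, int, int],  # (channels, height, width)
        cfg: ModelConfig = ModelConfig(),
        seed: int | None = None,
    ):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        ci, h, wd = input_shape
        for co, k in zip(cfg.channels, cfg.kernel_heights):
            scale = np.sqrt(2.0 / (ci * k))
            self.weights.append(rng.normal(0.0, scale, size=(co, ci, k)))
            self.biases.append(np.zeros(co))
            ci, h = co, h - k + 1
        n_flat = ci * h * wd
        self.w_out = rng.normal(0.0, np.sqrt(1.0 / n_flat), size=n_flat)
        self.b_out = np.zeros(1)
        self._rng = rng

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool):
        cache = []
        a = x
        for w, b in zip(self.weights, self.biases):
            z, windows = _conv_forward(a, w, b)
            mask = z > 0
            a = z * mask
            cache.append((windows, a.shape, mask, a))
        flat = a.reshape(a.shape[0], -1)
        if train and self.cfg.dropout_p > 0:
            drop = (
                self._rng.random(flat.shape) >= self.cfg.dropout_p
            ) / (1.0 - self.cfg.dropout_p)
            flat = flat * drop
        else:
            drop = None
        pred = flat @ self.w_out + self.b_out[0]
        return pred, (cache, flat, drop, x.shape)

    def predict(self, x: np.ndarray) -> np.ndarray:
        pred, _ = self._forward(x, train=False)
        return pred

    def _backward(self, dpred: np.ndarray, ctx):
        cache, flat, drop, x_shape = ctx
        grads_w: list[np.ndarray] = [None] * len(self.weights)
        grads_b: list[np.ndarray] = [None] * len(self.weights)
        dw_out = flat.T @ dpred
        db_out = np.array([dpred.sum()])
        dflat = np.outer(dpred, self.w_out)
        if drop is not None:
            dflat = dflat * drop
        windows, a_shape, mask, a = cache[-1]
        da = dflat.reshape(a_shape)
        for i in range(len(self.weights) - 1, -1, -1):
            windows, a_shape, mask, _a = cache[i]
            dz = da * mask
            prev_shape = x_shape if i == 0 else cache[i - 1][1]
            da, grads_w[i], grads_b[i] = _conv_backward(
                dz, windows, prev_shape, self.weights[i]
            )
        return grads_w, grads_b, dw_out, db_out

    # -- training -----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
    ) -> int:
        """Train with MSE + Adam; returns the number of epochs run.

        With a validation set, keeps the best-validation parameters and
        stops early after ``patience`` epochs without improvement.
        """
        cfg = self.cfg
        params = [*self.weights, *self.biases, self.w_out, self.b_out]
        opt = _Adam(params, cfg.learning_rate)
        best_val = np.inf
        best_params: list[np.ndarray] | None = None
        stall = 0
        epochs_run = 0
        n = len(y)
        for epoch in range(cfg.epochs):
            epochs_run = epoch + 1
            order = self._rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                pred, ctx = self._forward(x[idx], train=True)
                dpred = 2.0 * (pred - y[idx]) / len(idx)
                gw, gb, gwo, gbo = self._backward(dpred, ctx)
                opt.step(params, [*gw, *gb, gwo, gbo])
            if x_val is not None:
                val_loss = float(np.mean((self.predict(x_val) - y_val) ** 2))
                if val_loss < best_val - 1e-9:
                    best_val = val_loss
                    best_params = [p.copy() for p in params]
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience:
                        break
        if best_params is not None:
            for p, bp in zip(params, best_params):
                p[...] = bp
        return epochs_run


def _stack_images(images: Sequence[ReadImage] | np.ndarray) -> np.ndarray:
    if isinstance(images, np.ndarray):
        arr = images
    else:
        arr = np.stack([im.array for im in images])
    # (N, rows, cols, 2) -> (N, 2, rows, cols)
    return np.ascontiguousarray(arr.transpose(0, 3, 1, 2))


def train_and_predict(
    images: Sequence[ReadImage] | np.ndarray,
    targets: Sequence[float],
    cfg: ModelConfig = ModelConfig(),
    seed: int | None = None,
) -> PredictionResult:
    """Train on a seeded 50/50 split and predict the held-out half.

    Targets are standardized on the training half (and predictions mapped
    back) so the optimizer sees unit-scale residuals regardless of the
    expression units.  Fully deterministic for a fixed seed.
    """
    x = _stack_images(images)
    y = np.asarray(targets, dtype=float)
    if len(x) != len(y):
        raise ValueError("one target per image required")
    if len(y) < 64:
        raise ValueError("need >= 64 regions to train")
    if not np.all(np.isfinite(y)):
        raise ValueError("targets must be finite")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    n_train = int(round(len(y) * cfg.train_fraction))
    train_idx, test_idx = order[:n_train], order[n_train:]
    n_val = max(1, int(round(n_train * cfg.val_fraction)))
    val_idx, fit_idx = train_idx[:n_val], train_idx[n_val:]
    mu, sd = float(y[train_idx].mean()), float(y[train_idx].std())
    if sd == 0.0:
        sd = 1.0
    model = ConvRegressor(x.shape[1:], cfg, seed=int(rng.integers(2**31)))
    epochs_run = model.fit(
        x[fit_idx],
        (y[fit_idx] - mu) / sd,
        x[val_idx],
        (y[val_idx] - mu) / sd,
    )
    preds = model.predict(x[test_idx]) * sd + mu
    return PredictionResult(
        test_indices=test_idx,
        predictions=preds,
        test_targets=y[test_idx],
        train_indices=train_idx,
        epochs_run=epochs_run,
    )
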