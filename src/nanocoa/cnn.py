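"""Self-contained numpy implementation of the per-event 1D CNN.

Architecture: two 1D convolutional layers (10 filters of width 25, ReLU),
each followed by batch normalization and 20% dropout; max-pooling with
pool size 10; a dense layer with one output node per class and softmax.
Trained with Adam on the cross-entropy loss.

Forward and backward passes are written against an (N, L, F) layout
(batch, sequence position, filters) using im2col-style matmuls, which
keeps a full 100-epoch training run on a few hundred events in the
seconds-to-minutes range on one CPU core.
"""

from __future__ import annotations

import copy

import numpy as np


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sliding(x: np.ndarray, k: int) -> np.ndarray:
    """(N, L, C) -> (N, L-k+1, C*k) im2col along the sequence axis."""
    win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (N, L-k+1, C, k)
    n, lo, c, _ = win.shape
    return np.ascontiguousarray(win).reshape(n, lo, c * k)


class EventCNN:
    """Per-event cOA classifier (see module docstring for the layout)."""

    def __init__(
        self,
        n_classes: int,
        input_width: int = 251,
        n_filters: int = 10,
        kernel_width: int = 25,
        pool_size: int = 10,
        dropout: float = 0.2,
        bn_momentum: float = 0.9,
        seed: int | None = None,
    ) -> None:
        if n_classes < 2:
            raise ValueError("need at least 2 classes")
        l1 = input_width - kernel_width + 1
        l2 = l1 - kernel_width + 1
        if l2 < pool_size:
            raise ValueError(
                f"input_width={input_width} too small for two width-{kernel_width} "
                f"convolutions followed by pool size {pool_size}"
            )
        self.n_classes = n_classes
        self.input_width = input_width
        self.n_filters = n_filters
        self.kernel_width = kernel_width
        self.pool_size = pool_size
        self.dropout = dropout
        self.bn_momentum = bn_momentum
        self.l1, self.l2 = l1, l2
        self.pooled = l2 // pool_size
        self.n_features = n_filters * self.pooled
        self.reinitialize(np.random.default_rng(seed))

    # -- parameters ---------------------------------------------------------

    def reinitialize(self, rng: np.random.Generator) -> None:
        """Fresh He-normal weights and reset batch-norm statistics."""
        f, k = self.n_filters, self.kernel_width
        self.params = {
            "W1": rng.normal(0.0, np.sqrt(2.0 / k), size=(k, f)),
            "b1": np.zeros(f),
            "g1": np.ones(f),
            "be1": np.zeros(f),
            "W2": rng.normal(0.0, np.sqrt(2.0 / (f * k)), size=(f * k, f)),
            "b2": np.zeros(f),
            "g2": np.ones(f),
            "be2": np.zeros(f),
            "Wd": rng.normal(0.0, np.sqrt(2.0 / self.n_features), size=(self.n_features, self.n_classes)),
            "bd": np.zeros(self.n_classes),
        }
        self.running = {
            "mean1": np.zeros(f), "var1": np.ones(f),
            "mean2": np.zeros(f), "var2": np.ones(f),
        }

    def state_dict(self) -> dict:
        return {"params": copy.deepcopy(self.params), "running": copy.deepcopy(self.running)}

    def load_state_dict(self, state: dict) -> None:
        self.params = copy.deepcopy(state["params"])
        self.running = copy.deepcopy(state["running"])

    def architecture_summary(self) -> list[dict]:
        """One entry per layer, for introspection and manifests."""
        f, k = self.n_filters, self.kernel_width
        return [
            {"layer": "conv1d", "filters": f, "width": k, "activation": "relu"},
            {"layer": "batchnorm"},
            {"layer": "dropout", "rate": self.dropout},
            {"layer": "conv1d", "filters": f, "width": k, "activation": "relu"},
            {"layer": "batchnorm"},
            {"layer": "dropout", "rate": self.dropout},
            {"layer": "maxpool", "pool_size": self.pool_size},
            {"layer": "dense", "units": self.n_classes, "activation": "softmax"},
        ]

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    # -- forward ------------------------------------------------------------

    def _bn_forward(self, x, gamma, beta, mean_key, var_key, training, eps=1e-5):
        if training:
            mu = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            m = self.bn_momentum
            self.running[mean_key] = m * self.running[mean_key] + (1 - m) * mu
            self.running[var_key] = m * self.running[var_key] + (1 - m) * var
        else:
            mu, var = self.running[mean_key], self.running[var_key]
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv_std
        return xhat * gamma + beta, (xhat, inv_std)

    def _forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None):
        p = self.params
        cache: dict = {}
        n = x.shape[0]
        xin = x[:, :, None]  # (N, W, 1)

        cols1 = _sliding(xin, self.kernel_width)  # (N, L1, k)
        z1 = cols1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)
        h1, bn1 = self._bn_forward(a1, p["g1"], p["be1"], "mean1", "var1", training)
        if training and self.dropout > 0:
            mask1 = (rng.random(h1.shape) >= self.dropout) / (1 - self.dropout)
            d1 = h1 * mask1
        else:
            mask1, d1 = None, h1

        cols2 = _sliding(d1, self.kernel_width)  # (N, L2, f*k)
        z2 = cols2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)
        h2, bn2 = self._bn_forward(a2, p["g2"], p["be2"], "mean2", "var2", training)
        if training and self.dropout > 0:
            mask2 = (rng.random(h2.shape) >= self.dropout) / (1 - self.dropout)
            d2 = h2 * mask2
        else:
            mask2, d2 = None, h2

        lp = self.pooled * self.pool_size
        tiles = d2[:, :lp, :].reshape(n, self.pooled, self.pool_size, self.n_filters)
        amax = tiles.argmax(axis=2)
        pooled = np.take_along_axis(tiles, amax[:, :, None, :], axis=2)[:, :, 0, :]
        flat = pooled.reshape(n, self.n_features)
        logits = flat @ p["Wd"] + p["bd"]
        probs = softmax(logits)

        cache.update(
            cols1=cols1, z1=z1, bn1=bn1, mask1=mask1,
            cols2=cols2, z2=z2, bn2=bn2, mask2=mask2,
            amax=amax, flat=flat, tiles_shape=tiles.shape,
        )
        return probs, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities (eval mode: running BN statistics, no dropout)."""
        probs, _ = self._forward(np.asarray(x, dtype=float), training=False, rng=None)
        return probs

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    # -- backward -----------------------------------------------------------

    @staticmethod
    def _bn_backward(dy, gamma, bn_cache):
        xhat, inv_std = bn_cache
        m = dy.shape[0] * dy.shape[1]
        dgamma = (dy * xhat).sum(axis=(0, 1))
        dbeta = dy.sum(axis=(0, 1))
        dxhat = dy * gamma
        dx = (inv_std / m) * (
            m * dxhat - dxhat.sum(axis=(0, 1)) - xhat * (dxhat * xhat).sum(axis=(0, 1))
        )
        return dx, dgamma, dbeta

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        p = self.params
        n = probs.shape[0]
        grads: dict = {}

        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads["Wd"] = cache["flat"].T @ dlogits
        grads["bd"] = dlogits.sum(axis=0)
        dflat = dlogits @ p["Wd"].T
        dpooled = dflat.reshape(n, self.pooled, self.n_filters)

        dtiles = np.zeros(cache["tiles_shape"])
        np.put_along_axis(dtiles, cache["amax"][:, :, None, :], dpooled[:, :, None, :], axis=2)
        dd2 = np.zeros((n, self.l2, self.n_filters))
        dd2[:, : self.pooled * self.pool_size, :] = dtiles.reshape(n, -1, self.n_filters)

        if cache["mask2"] is not None:
            dd2 = dd2 * cache["mask2"]
        dh2, grads["g2"], grads["be2"] = self._bn_backward(dd2, p["g2"], cache["bn2"])
        dz2 = dh2 * (cache["z2"] > 0)
        cols2 = cache["cols2"]
        grads["W2"] = cols2.reshape(-1, cols2.shape[2]).T @ dz2.reshape(-1, self.n_filters)
        grads["b2"] = dz2.sum(axis=(0, 1))
        dcols2 = (dz2 @ p["W2"].T).reshape(n, self.l2, self.n_filters, self.kernel_width)
        dd1 = np.zeros((n, self.l1, self.n_filters))
        for k in range(self.kernel_width):
            dd1[:, k : k + self.l2, :] += dcols2[:, :, :, k]

        if cache["mask1"] is not None:
            dd1 = dd1 * cache["mask1"]
        dh1, grads["g1"], grads["be1"] = self._bn_backward(dd1, p["g1"], cache["bn1"])
        dz1 = dh1 * (cache["z1"] > 0)
        cols1 = cache["cols1"]
        grads["W1"] = cols1.reshape(-1, self.kernel_width).T @ dz1.reshape(-1, self.n_filters)
        grads["b1"] = dz1.sum(axis=(0, 1))
        return grads

    # -- training -----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        rng: np.random.Generator | None = None,
        oversample: bool = True,
    ) -> list[dict]:
        """One training run; returns a per-epoch log of loss and accuracy.

        When *oversample* is on, minority classes are re-drawn with
        replacement up to the majority count before each epoch, so every
        epoch sees balanced classes.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        rng = np.random.default_rng() if rng is None else rng
        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        log: list[dict] = []
        for epoch in range(epochs):
            idx = _oversample_indices(y, rng) if oversample else np.arange(y.size)
            rng.shuffle(idx)
            losses, n_correct, n_seen = [], 0, 0
            for lo in range(0, idx.size, batch_size):
                batch = idx[lo : lo + batch_size]
                if batch.size < 2:
                    continue  # batch norm needs > 1 sample
                xb, yb = x[batch], y[batch]
                probs, cache = self._forward(xb, training=True, rng=rng)
                loss = -np.mean(np.log(probs[np.arange(yb.size), yb] + 1e-12))
                grads = self._backward(probs, yb, cache)
                step += 1
                for key, g in grads.items():
                    adam_m[key] = beta1 * adam_m[key] + (1 - beta1) * g
                    adam_v[key] = beta2 * adam_v[key] + (1 - beta2) * g * g
                    mhat = adam_m[key] / (1 - beta1**step)
                    vhat = adam_v[key] / (1 - beta2**step)
                    self.params[key] -= learning_rate * mhat / (np.sqrt(vhat) + eps)
                losses.append(loss)
                n_correct += int((probs.argmax(axis=1) == yb).sum())
                n_seen += yb.size
            log.append(
                {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": n_correct / max(n_seen, 1)}
            )
        return log

    def accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(x) == np.asarray(y)))


def _oversample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices with minority classes duplicated up to the majority count."""
    classes, counts = np.unique(y, return_counts=True)
    majority = counts.max()
    parts = []
    for cls, count in zip(classes, counts):
        members = np.flatnonzero(y == cls)
        parts.append(members)
        if count < majority:
            parts.append(rng.choice(members, size=majority - count, replace=True))
    return np.concatenate(parts)
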