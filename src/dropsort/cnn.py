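"""Minimal NumPy engine for the shallow viability CNN.

The networks used for nozzle-image viability prediction are tiny — two 3x3
convolutions (each followed by 2x2 max-pooling), one fully connected hidden
layer, and a single sigmoid output — and train on hundreds of 55x55 crops.
At that scale a vectorized NumPy implementation trains in seconds on one CPU
core, keeps the package dependency-light, and makes every gradient explicit.

Layout is channels-last: batches are (N, H, W, C).  Convolutions are stride-1
with same-padding; pooling is 2x2 stride 2 (floor).  The loss is
class-weighted binary cross-entropy on logits; the optimizer is Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["ShallowCNN", "sigmoid", "weighted_bce"]

_K = 3  # conv kernel edge


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def weighted_bce(logits: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Mean weighted binary cross-entropy, computed stably from logits."""
    z, y, w = logits.ravel(), y.ravel(), w.ravel()
    # log(1+e^z) without overflow
    softplus = np.maximum(z, 0) + np.log1p(np.exp(-np.abs(z)))
    losses = softplus - y * z
    return float(np.mean(w * losses))


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,H,W,C), padded by 1 -> (N*H*W, 9*C) patch matrix."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (_K, _K), axis=(1, 2))  # (N,H,W,C,3,3)
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, _K * _K * c)


def _col2im(dcol: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of _im2col: scatter-add patch gradients back to image grads."""
    n, h, w, c = shape
    d = dcol.reshape(n, h, w, _K, _K, c)
    dxp = np.zeros((n, h + 2, w + 2, c))
    for di in range(_K):
        for dj in range(_K):
            dxp[:, di : di + h, dj : dj + w, :] += d[:, :, :, di, dj, :]
    return dxp[:, 1:-1, 1:-1, :]


def _pool_forward(x: np.ndarray):
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xc = x[:, : h2 * 2, : w2 * 2, :]
    patches = (
        xc.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4).reshape(n, h2, w2, c, 4)
    )
    idx = np.argmax(patches, axis=-1)
    out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
    return out, (idx, x.shape)


def _pool_backward(dout: np.ndarray, cache) -> np.ndarray:
    idx, (n, h, w, c) = cache
    h2, w2 = h // 2, w // 2
    dpatch = np.zeros((n, h2, w2, c, 4))
    np.put_along_axis(dpatch, idx[..., None], dout[..., None], axis=-1)
    dxc = dpatch.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3).reshape(
        n, h2 * 2, w2 * 2, c
    )
    dx = np.zeros((n, h, w, c))
    dx[:, : h2 * 2, : w2 * 2, :] = dxc
    return dx


class ShallowCNN:
    """conv(F)->pool->conv(F)->pool->flatten->FC(D)->ReLU->FC(1) on 55x55x1 crops.

    ``conv_filters`` (F) and ``fc_nodes`` (D) are the two capacity knobs; the
    canonical configurations are 4/32 and 32/128.
    """

    INPUT_SHAPE = (55, 55, 1)

    def __init__(self, conv_filters: int, fc_nodes: int, seed: int = 0):
        if conv_filters < 1 or fc_nodes < 1:
            raise ValueError("conv_filters and fc_nodes must be positive")
        self.conv_filters = int(conv_filters)
        self.fc_nodes = int(fc_nodes)
        h, w, cin = self.INPUT_SHAPE
        h1, w1 = h // 2, w // 2  # after pool1: 27
        h2, w2 = h1 // 2, w1 // 2  # after pool2: 13
        self._flat = h2 * w2 * conv_filters
        rng = np.random.default_rng(seed)
        f = conv_filters

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "W1": he((_K, _K, cin, f), _K * _K * cin),
            "b1": np.zeros(f),
            "W2": he((_K, _K, f, f), _K * _K * f),
            "b2": np.zeros(f),
            "W3": he((self._flat, fc_nodes), self._flat),
            "b3": np.zeros(fc_nodes),
            "W4": he((fc_nodes, 1), fc_nodes),
            "b4": np.zeros(1),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -----------------------------------------------------------

    def _conv(self, x, W, b):
        n, h, w, _ = x.shape
        f = W.shape[-1]
        col = _im2col(x)
        out = col @ W.reshape(-1, f) + b
        return out.reshape(n, h, w, f), col

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Logits for a batch of crops shaped (N, 55, 55, 1)."""
        if x.ndim != 4 or x.shape[1:] != self.INPUT_SHAPE:
            raise ValueError(
                f"expected batch of shape (N, 55, 55, 1), got {x.shape}"
            )
        # crops arrive in [0,1] with the background at 0.5; center it at zero
        # so activations are signal-driven rather than bias-dominated
        x = x - 0.5
        p = self.params
        z1, col1 = self._conv(x, p["W1"], p["b1"])
        a1 = np.maximum(z1, 0)
        p1, pc1 = _pool_forward(a1)
        z2, col2 = self._conv(p1, p["W2"], p["b2"])
        a2 = np.maximum(z2, 0)
        p2, pc2 = _pool_forward(a2)
        flat = p2.reshape(x.shape[0], -1)
        z3 = flat @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0)
        logits = a3 @ p["W4"] + p["b4"]
        if not want_cache:
            return logits
        cache = (x, col1, z1, pc1, p1, col2, z2, pc2, p2, flat, z3, a3)
        return logits, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x)).ravel()

    # -- backward ----------------------------------------------------------

    def backward(self, cache, logits, y, w):
        """Gradients of mean weighted BCE w.r.t. every parameter."""
        x, col1, z1, pc1, p1, col2, z2, pc2, p2, flat, z3, a3 = cache
        p = self.params
        n = x.shape[0]
        f = self.conv_filters

        dz4 = (w.reshape(-1, 1) * (sigmoid(logits) - y.reshape(-1, 1))) / n
        grads = {
            "W4": a3.T @ dz4,
            "b4": dz4.sum(0),
        }
        da3 = dz4 @ p["W4"].T
        dz3 = da3 * (z3 > 0)
        grads["W3"] = flat.T @ dz3
        grads["b3"] = dz3.sum(0)
        dflat = dz3 @ p["W3"].T
        dp2 = dflat.reshape(p2.shape)
        da2 = _pool_backward(dp2, pc2)
        dz2 = da2 * (z2 > 0)
        dz2m = dz2.reshape(-1, f)
        grads["W2"] = (col2.T @ dz2m).reshape(p["W2"].shape)
        grads["b2"] = dz2m.sum(0)
        dcol2 = dz2m @ p["W2"].reshape(-1, f).T
        dp1 = _col2im(dcol2, p1.shape)
        da1 = _pool_backward(dp1, pc1)
        dz1 = da1 * (z1 > 0)
        dz1m = dz1.reshape(-1, f)
        grads["W1"] = (col1.T @ dz1m).reshape(p["W1"].shape)
        grads["b1"] = dz1m.sum(0)
        return grads

    def adam_step(self, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g * g
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- (de)serialization of raw parameters --------------------------------

    def state_dict(self) -> dict:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k in self.params:
            if k not in state:
                raise KeyError(f"missing parameter {k!r} in state dict")
            if state[k].shape != self.params[k].shape:
                raise ValueError(
                    f"shape mismatch for {k!r}: {state[k].shape} vs {self.params[k].shape}"
                )
            self.params[k] = np.array(state[k], dtype=float)
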