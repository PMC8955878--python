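"""A small temporal convolutional network in plain numpy.

This is the inference/training engine behind the exercise and anomaly
classifiers: two 1-D convolutions over the time axis (channels-last),
max-pooling, global average pooling, one dense layer, and a task head
(6-way softmax or 1-unit sigmoid).  At the default widths the whole model
holds ~1,100 parameters, small enough for microcontroller-class inference,
and trains in seconds on a CPU with the Adam optimizer implemented below.

Shapes: inputs are ``(B, Ns, C)`` batches of scaled window matrices;
convolutions are "valid" (no padding), so Ns >= 10 is required for the
default pooling layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["LayerSizes", "TinyConvNet", "AdamOptimizer"]


@dataclass(frozen=True)
class LayerSizes:
    """Widths of the shared trunk and head."""

    conv_filters: tuple[int, int] = (16, 8)
    conv_width: int = 3
    pool: int = 2
    dense: int = 16


def _im2col(x: np.ndarray, w: int) -> np.ndarray:
    """(B, L, C) -> (B, L-w+1, w*C) patches for valid 1-D convolution."""
    # sliding_window_view over the time axis gives (B, L-w+1, C, w)
    v = sliding_window_view(x, w, axis=1)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - w + 1, w * x.shape[2]
    )


class AdamOptimizer:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            m = self.m[k] = b1 * self.m[k] + (1 - b1) * g
            v = self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            params[k] -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


class TinyConvNet:
    """conv(F1,w) -> maxpool -> conv(F2,w) -> GAP -> dense -> head.

    ``n_out=1`` builds the sigmoid anomaly head; ``n_out>1`` the softmax
    exercise head.  The trunk (everything below the head) is identical
    across tasks at equal input shape, so trunk weights transfer between
    the exercise and anomaly models (warm start).
    """

    TRUNK_KEYS = ("W1", "b1", "W2", "b2", "W3", "b3")

    def __init__(self, ns: int, n_channels: int, n_out: int,
                 sizes: LayerSizes = LayerSizes(),
                 rng: np.random.Generator | None = None):
        if ns < 2 * sizes.conv_width + 2 * sizes.pool:
            raise ValueError(f"window Ns={ns} too short for this layout")
        self.ns = ns
        self.n_channels = n_channels
        self.n_out = n_out
        self.sizes = sizes
        rng = rng or np.random.default_rng()
        f1, f2 = sizes.conv_filters
        w = sizes.conv_width

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(np.float64)

        self.params: dict[str, np.ndarray] = {
            "W1": he((w * n_channels, f1), w * n_channels),
            "b1": np.zeros(f1),
            "W2": he((w * f1, f2), w * f1),
            "b2": np.zeros(f2),
            "W3": he((f2, sizes.dense), f2),
            "b3": np.zeros(sizes.dense),
            "W4": he((sizes.dense, n_out), sizes.dense),
            "b4": np.zeros(n_out),
        }

    # -- bookkeeping -----------------------------------------------------

    @property
    def param_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def copy_trunk_from(self, other: "TinyConvNet") -> None:
        """Warm start: copy trunk weights from a model of equal geometry."""
        if (other.ns, other.n_channels, other.sizes) != (
                self.ns, self.n_channels, self.sizes):
            raise ValueError("trunk geometries differ; cannot transfer weights")
        for k in self.TRUNK_KEYS:
            self.params[k] = other.params[k].copy()

    # -- forward ---------------------------------------------------------

    def forward(self, x: np.ndarray, cache: bool = False):
        """Head activations for a batch (B, Ns, C): softmax rows or sigmoid scalars."""
        p = self.params
        w = self.sizes.conv_width
        pool = self.sizes.pool

        c1 = _im2col(x, w)
        z1 = c1 @ p["W1"] + p["b1"]
        a1 = np.maximum(z1, 0.0)

        L = a1.shape[1] - a1.shape[1] % pool
        a1p = a1[:, :L].reshape(a1.shape[0], L // pool, pool, -1)
        m1 = a1p.max(axis=2)

        c2 = _im2col(m1, w)
        z2 = c2 @ p["W2"] + p["b2"]
        a2 = np.maximum(z2, 0.0)

        g = a2.mean(axis=1)
        z3 = g @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        z4 = a3 @ p["W4"] + p["b4"]

        if self.n_out == 1:
            out = 1.0 / (1.0 + np.exp(-z4))
        else:
            e = np.exp(z4 - z4.max(axis=1, keepdims=True))
            out = e / e.sum(axis=1, keepdims=True)
        if not cache:
            return out
        return out, {"x": x, "c1": c1, "z1": z1, "a1": a1, "a1p": a1p,
                     "L": L, "m1": m1, "c2": c2, "z2": z2, "a2": a2,
                     "g": g, "a3": a3, "z3": z3}

    def predict(self, x: np.ndarray, chunk: int = 8192) -> np.ndarray:
        """Chunked forward pass for large window batches."""
        outs = [self.forward(x[i:i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(outs, axis=0)

    # -- loss + backward -------------------------------------------------

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy loss and parameter gradients for one batch.

        ``y`` holds integer class indices (softmax head) or 0/1 floats
        (sigmoid head).  The head gradient ``(p - y)/B`` is shared by both
        losses, which is what makes the two heads interchangeable on one
        trunk.
        """
        out, cc = self.forward(x, cache=True)
        B = len(x)
        eps = 1e-12
        if self.n_out == 1:
            yf = np.asarray(y, dtype=float).reshape(-1, 1)
            loss = -np.mean(yf * np.log(out + eps) + (1 - yf) * np.log(1 - out + eps))
            dz4 = (out - yf) / B
        else:
            idx = np.asarray(y, dtype=int)
            loss = -np.mean(np.log(out[np.arange(B), idx] + eps))
            dz4 = out.copy()
            dz4[np.arange(B), idx] -= 1.0
            dz4 /= B

        p = self.params
        grads: dict[str, np.ndarray] = {}
        grads["W4"] = cc["a3"].T @ dz4
        grads["b4"] = dz4.sum(axis=0)
        da3 = dz4 @ p["W4"].T
        dz3 = da3 * (cc["z3"] > 0)
        grads["W3"] = cc["g"].T @ dz3
        grads["b3"] = dz3.sum(axis=0)
        dg = dz3 @ p["W3"].T

        T2 = cc["a2"].shape[1]
        da2 = np.repeat(dg[:, None, :], T2, axis=1) / T2
        dz2 = da2 * (cc["z2"] > 0)
        grads["W2"] = cc["c2"].reshape(-1, cc["c2"].shape[-1]).T @ \
            dz2.reshape(-1, dz2.shape[-1])
        grads["b2"] = dz2.sum(axis=(0, 1))
        dc2 = dz2 @ p["W2"].T

        dm1 = self._col2im(dc2, cc["m1"].shape)
        da1 = np.zeros_like(cc["a1"])
        pool = self.sizes.pool
        L = cc["L"]
        # route pooled gradients back to the max positions (float ties are
        # measure-zero, so the equality mask selects one winner in practice)
        mask = cc["a1p"] == cc["m1"][:, :, None, :]
        da1[:, :L] = (mask * dm1[:, :, None, :]).reshape(da1.shape[0], L, -1)

        dz1 = da1 * (cc["z1"] > 0)
        grads["W1"] = cc["c1"].reshape(-1, cc["c1"].shape[-1]).T @ \
            dz1.reshape(-1, dz1.shape[-1])
        grads["b1"] = dz1.sum(axis=(0, 1))
        return float(loss), grads

    def _col2im(self, dcols: np.ndarray, out_shape: tuple) -> np.ndarray:
        """Adjoint of _im2col: scatter-add patch gradients (w iterations)."""
        w = self.sizes.conv_width
        B, P, _ = dcols.shape
        C = out_shape[2]
        d = dcols.reshape(B, P, w, C)
        dx = np.zeros(out_shape)
        for j in range(w):
            dx[:, j:j + P, :] += d[:, :, j, :]
        return dx
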