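"""Minimal neural-network primitives (NumPy, channel-last layout).

Just enough machinery for the two-branch classifier: 1-D convolution via
im2col, non-overlapping average pooling, leaky-rectifier and sigmoid
activations, dense layers, and an Adam optimizer with decoupled-from-bias L2
weight decay.  Arrays are (batch, length, channels) for sequence data.
All forward functions return what backward needs; no autograd.
"""

from __future__ import annotations

import numpy as np


def leaky_relu(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, z, slope * z)


def leaky_relu_grad(z: np.ndarray, slope: float) -> np.ndarray:
    return np.where(z > 0, 1.0, slope)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def im2col1d(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, L, C) -> (N, L_out, k*C) patch matrix with zero padding."""
    n, length, c = x.shape
    if pad:
        x = np.concatenate(
            [np.zeros((n, pad, c), x.dtype), x, np.zeros((n, pad, c), x.dtype)], axis=1
        )
    l_out = x.shape[1] - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (N, L_out, C, k)
    return windows.transpose(0, 1, 3, 2).reshape(n, l_out, k * c)


def col2im1d(dpatches: np.ndarray, k: int, pad: int, length: int, channels: int) -> np.ndarray:
    """Adjoint of :func:`im2col1d`: scatter patch gradients back to (N, L, C)."""
    n, l_out, _ = dpatches.shape
    dp = dpatches.reshape(n, l_out, k, channels)
    dx = np.zeros((n, length + 2 * pad, channels), dpatches.dtype)
    for j in range(k):
        dx[:, j : j + l_out, :] += dp[:, :, j, :]
    return dx[:, pad : pad + length, :] if pad else dx


def conv1d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, pad: int):
    """x (N, L, C_in), w (C_out, k*C_in) -> z (N, L_out, C_out), cache."""
    patches = im2col1d(x, k=_kernel_width(w, x.shape[2]), pad=pad)
    z = patches @ w.T + b
    return z, patches


def _kernel_width(w: np.ndarray, c_in: int) -> int:
    k, rem = divmod(w.shape[1], c_in)
    if rem:
        raise ValueError("kernel matrix width is not a multiple of input channels")
    return k


def conv1d_backward(dz: np.ndarray, patches: np.ndarray, w: np.ndarray, pad: int, length: int, c_in: int):
    """Gradients for conv1d: returns (dx, dw, db)."""
    n, l_out, c_out = dz.shape
    dz2 = dz.reshape(-1, c_out)
    dw = dz2.T @ patches.reshape(-1, patches.shape[2])
    db = dz2.sum(axis=0)
    dpatches = (dz2 @ w).reshape(n, l_out, patches.shape[2])
    dx = col2im1d(dpatches, k=_kernel_width(w, c_in), pad=pad, length=length, channels=c_in)
    return dx, dw, db


def avgpool_forward(x: np.ndarray, width: int) -> np.ndarray:
    """Non-overlapping average pooling along length; remainder dropped."""
    n, length, c = x.shape
    l_out = length // width
    return x[:, : l_out * width, :].reshape(n, l_out, width, c).mean(axis=2)


def avgpool_backward(dy: np.ndarray, width: int, length: int) -> np.ndarray:
    n, l_out, c = dy.shape
    dx = np.zeros((n, length, c), dy.dtype)
    expanded = np.repeat(dy / width, width, axis=1)
    dx[:, : l_out * width, :] = expanded
    return dx


def bce_loss(p: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class Adam:
    """Adam with optional per-parameter L2 weight decay added to the gradient."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, l2: float = 0.0,
                 decay_params: set | None = None):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps, self.l2 = lr, beta1, beta2, eps, l2
        self.decay_params = decay_params if decay_params is not None else set(params)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            if self.l2 and k in self.decay_params:
                g = g + self.l2 * p
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
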