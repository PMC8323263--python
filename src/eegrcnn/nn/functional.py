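"""Low-level numerical ops for the 1-D CNN + indRNN stack.

Convolutions use "same" padding (TensorFlow convention: output length
``ceil(T / stride)``, surplus padding on the right) and are evaluated as a
single GEMM over an im2col matrix; the backward pass scatters gradients back
with one strided accumulation per kernel tap. Everything is float32.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def same_pad_amounts(t: int, k: int, s: int) -> tuple[int, int, int]:
    """(out_len, pad_left, pad_right) for same-padded conv of length ``t``."""
    out = -(-t // s)  # ceil
    pad_total = max((out - 1) * s + k - t, 0)
    left = pad_total // 2
    return out, left, pad_total - left


def im2col(x: np.ndarray, k: int, s: int) -> tuple[np.ndarray, int, int]:
    """Unfold ``x`` (B, C, T) into (B*out, C*k) columns with same padding.

    Returns (cols, out_len, pad_left).
    """
    b, c, t = x.shape
    out, left, right = same_pad_amounts(t, k, s)
    if left or right:
        xp = np.pad(x, ((0, 0), (0, 0), (left, right)))
    else:
        xp = x
    windows = sliding_window_view(xp, k, axis=2)[:, :, ::s, :]  # (B, C, out, k)
    cols = windows.transpose(0, 2, 1, 3).reshape(b * out, c * k)
    return np.ascontiguousarray(cols), out, left


def col2im(
    dcols: np.ndarray, x_shape: tuple[int, int, int], k: int, s: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add column grads back to (B, C, T)."""
    b, c, t = x_shape
    out, left, right = same_pad_amounts(t, k, s)
    d4 = dcols.reshape(b, out, c, k)
    dxp = np.zeros((b, c, t + left + right), dtype=dcols.dtype)
    for j in range(k):
        dxp[:, :, j : j + s * (out - 1) + 1 : s] += d4[:, :, :, j].transpose(0, 2, 1)
    return dxp[:, :, left : left + t]


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


def leaky_relu_grad(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x >= 0, np.float32(1.0), np.float32(slope))


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise stable softmax."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross-entropy of integer targets ``y``."""
    p = probs[np.arange(y.size), y]
    return float(-np.mean(np.log(np.maximum(p, eps))))


def conv_out_len(t: int, s: int) -> int:
    return -(-t // s)


def chain_out_len(input_len: int, n_stride2: int = 3, avg_pool: int = 2) -> int:
    """Time length after ``n_stride2`` same-padded stride-2 stages + pooling."""
    t = input_len
    for _ in range(n_stride2):
        t = conv_out_len(t, 2)
    if avg_pool > 1:
        t = t // avg_pool
    return t
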