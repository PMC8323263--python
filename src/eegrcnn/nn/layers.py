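"""Trainable layers: 1-D convolution, batch norm, pooling, dense, indRNN.

Layers follow a minimal forward/backward protocol: ``forward(x, training)``
caches what the adjoint needs, ``backward(dy)`` accumulates parameter
gradients and returns the input gradient.

Feature maps are channels-last ``(batch, time, channels)`` float32 and kept
C-contiguous at every layer boundary. Convolutions are same-padded and
evaluated as BLAS-accumulated GEMMs, one per kernel tap and stride phase,
over the flattened (batch*time, channels) matrix — no im2col on the forward
or input-gradient path. Elementwise-heavy steps (batch norm, LeakyReLU, the
indRNN recurrence) are numba-jitted single-pass kernels writing into
per-layer reusable buffers, so a training step allocates almost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.linalg import blas as _blas

from ..exceptions import ValidationError
from . import functional as F


class Param:
    """A trainable array with its gradient and optional absolute-value bound."""

    __slots__ = ("data", "grad", "name", "clip_abs")

    def __init__(self, data: np.ndarray, name: str = "", clip_abs: float | None = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name
        self.clip_abs = clip_abs

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class _BufferPool:
    """Reusable float32 scratch arrays keyed by name; one shape per name."""

    def __init__(self):
        self._bufs: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple, zero: bool = False) -> np.ndarray:
        """Fetch a buffer; ``zero`` only zero-fills on (re)allocation.

        Buffers are kept per (name, shape) so alternating batch sizes
        (full batches vs the trailing partial one) do not reallocate.
        """
        key = (name, shape)
        buf = self._bufs.get(key)
        if buf is None:
            buf = np.zeros(shape, np.float32) if zero else np.empty(shape, np.float32)
            self._bufs[key] = buf
        return buf


_colsum_ones: dict[int, np.ndarray] = {}


def _colsum(a: np.ndarray) -> np.ndarray:
    """Per-column sum of a C-contiguous 2-D float32 matrix via BLAS."""
    m = a.shape[0]
    ones = _colsum_ones.get(m)
    if ones is None:
        ones = np.ones(m, dtype=np.float32)
        _colsum_ones[m] = ones
    return _blas.sgemv(1.0, a.T, ones, trans=0)


def _gemm_into(a: np.ndarray, b: np.ndarray, c: np.ndarray, beta: float) -> None:
    """c = beta*c + a @ b without temporaries (C-ordered operands).

    Uses the identity (A@B)^T = B^T A^T so the BLAS call sees
    Fortran-contiguous views and writes in place.
    """
    _blas.sgemm(1.0, b.T, a.T, beta=beta, c=c.T, overwrite_c=True)


class Conv1d(Layer):
    """Same-padded 1-D convolution, (B, T, C_in) -> (B, ceil(T/stride), F)."""

    def __init__(
        self,
        c_in: int,
        filters: int,
        kernel: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        need_input_grad: bool = True,
        name: str = "conv1d",
    ):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel
        w = rng.standard_normal((kernel, c_in, filters)) * np.sqrt(2.0 / fan_in)
        self.W = Param(w, name=f"{name}.W")  # (k, C_in, F), tap-major
        self.b = Param(np.zeros(filters), name=f"{name}.b")
        self.kernel, self.stride = kernel, stride
        self.c_in, self.filters = c_in, filters
        self.need_input_grad = need_input_grad
        self._cache: tuple | None = None
        self._pool = _BufferPool()

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def _taps(self, phase: int) -> range:
        return range(phase, self.kernel, self.stride)

    @property
    def _small_k(self) -> bool:
        # tiny fan-in convs (e.g. the 1-channel input layer) run faster as a
        # single im2col GEMM than as rank-C tap accumulations
        return self.c_in * self.kernel <= 16 and not self.need_input_grad

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        b, t, c = x.shape
        if c != self.c_in:
            raise ValidationError(f"expected {self.c_in} input channels, got {c}")
        k, s = self.kernel, self.stride
        t_out, left, right = F.same_pad_amounts(t, k, s)
        t_ph = -(-(t + left + right) // s)  # phase buffer length per batch
        if self._small_k:
            xp = self._pool.get("xp", (b, t + left + right, c), zero=True)
            xp[:, left : left + t] = x
            xf = xp.reshape(b, -1)
            cols = self._pool.get("cols", (b * t_out, k * c))
            view = np.lib.stride_tricks.as_strided(
                xf,
                shape=(b, t_out, k * c),
                strides=(xf.strides[0], s * c * 4, 4),
            )
            np.copyto(cols.reshape(b, t_out, k * c), view)
            out = self._pool.get("out", (b, t_out, self.filters))
            _gemm_into(cols, self.W.data.reshape(k * c, self.filters),
                       out.reshape(-1, self.filters), beta=0.0)
            out += self.b.data
            self.last_stats = None
            self._cache = ((b, t, c), t_out, left, t_ph)
            return out
        phases = [
            self._pool.get(f"ph{p}", (b, t_ph, c), zero=True) for p in range(s)
        ]
        if s == 1:
            phases[0][:, left : left + t] = x
        else:
            for p in range(s):
                # phase sample m sits at padded coordinate q = s*m + p,
                # i.e. input coordinate q - left
                m0 = max(0, -(-(left - p) // s))
                q0 = s * m0 + p - left
                src = x[:, q0::s, :]
                phases[p][:, m0 : m0 + src.shape[1]] = src
        y = self._pool.get("y", (b, t_ph, self.filters))
        yf = y.reshape(-1, self.filters)
        first = True
        for p in range(s):
            pf = phases[p].reshape(-1, c)
            for i, j in enumerate(self._taps(p)):
                r = pf.shape[0] - i
                _gemm_into(pf[i : i + r], self.W.data[j],
                           yf[:r], beta=0.0 if first else 1.0)
                first = False
        out = self._pool.get("out", (b, t_out, self.filters))
        # bias add, gather to contiguous, and batch-norm statistics in one pass
        self.last_stats = _copy_bias_stats(y, t_out, self.b.data, out)
        self._cache = ((b, t, c), t_out, left, t_ph)
        return out

    @property
    def supports_grad_into(self) -> bool:
        return not self._small_k

    def grad_buffer(self) -> tuple[np.ndarray, int]:
        """(g, t_out): the gradient-output buffer an upstream layer may fill."""
        (b, t, c), t_out, left, t_ph = self._cache
        return self._pool.get("g", (b, t_ph, self.filters), zero=True), t_out

    def backward(self, dy: np.ndarray | None) -> np.ndarray:
        """Backward pass; ``dy=None`` means the g buffer was filled upstream."""
        (b, t, c), t_out, left, t_ph = self._cache
        k, s = self.kernel, self.stride
        if self._small_k:
            dy = np.ascontiguousarray(dy)
            self.b.grad += _colsum(dy.reshape(-1, self.filters))
            cols = self._pool.get("cols", (b * t_out, k * c))
            dw = dy.reshape(-1, self.filters).T @ cols  # (F, k*C)
            self.W.grad += dw.T.reshape(k, c, self.filters)
            return np.zeros((b, t, c), dtype=np.float32)
        g = self._pool.get("g", (b, t_ph, self.filters), zero=True)
        if dy is not None:
            g[:, :t_out] = dy
        gf = g.reshape(-1, self.filters)
        self.b.grad += _colsum(gf)  # zero tail rows do not perturb the sum
        dphases = []
        for p in range(s):
            taps = list(self._taps(p))
            n_taps = len(taps)
            pf = self._pool.get(f"ph{p}", (b, t_ph, c)).reshape(-1, c)
            if n_taps:
                # one GEMM for all taps of this phase, over the shift-stacked view
                r = pf.shape[0] - (n_taps - 1)
                shifted = np.lib.stride_tricks.as_strided(
                    pf,
                    shape=(r, n_taps, c),
                    strides=(pf.strides[0], pf.strides[0], pf.strides[1]),
                )
                cols = self._pool.get(f"cols{p}", (r, n_taps * c))
                np.copyto(cols.reshape(r, n_taps, c), shifted)
                dw = gf[:r].T @ cols  # (F, taps*C)
                dw3 = dw.reshape(self.filters, n_taps, c).transpose(1, 2, 0)
                for i, j in enumerate(taps):
                    self.W.grad[j] += dw3[i]
            if self.need_input_grad:
                dpf = self._pool.get(f"dph{p}", (b, t_ph, c)).reshape(-1, c)
                if not taps:
                    dpf[:, :] = 0.0
                # tap i=0 covers every row with beta=0; later taps accumulate
                for i, j in enumerate(taps):
                    r = pf.shape[0] - i
                    _gemm_into(gf[:r], self.W.data[j].T, dpf[i : i + r],
                               beta=0.0 if i == 0 else 1.0)
                dphases.append(dpf.reshape(b, t_ph, c))
        if not self.need_input_grad:
            return np.zeros((b, t, c), dtype=np.float32)
        # returned as a view into reusable scratch: valid until the next
        # backward pass through this layer
        if s == 1:
            return dphases[0][:, left : left + t]
        dxp = self._pool.get("dxp", (b, t_ph * s, c))
        for p in range(s):
            dxp[:, p :: s] = dphases[p]
        return dxp[:, left : left + t]


# --- fused batch norm / activation kernels (2-D contiguous, out-params) ----


@njit(cache=True, fastmath=True)
def _bn_stats(x):  # per-channel sum and sum of squares over rows
    m, c = x.shape
    s = np.zeros(c, dtype=np.float64)
    sq = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for l in range(c):
            v = np.float64(x[i, l])
            s[l] += v
            sq[l] += v * v
    return s, sq


@njit(cache=True, fastmath=True)
def _copy_bias_stats(y, t_out, bias, out):
    """out = y[:, :t_out] + bias, plus per-channel sum/sumsq, one pass."""
    b, t_ph, f = y.shape
    s = np.zeros(f, dtype=np.float64)
    sq = np.zeros(f, dtype=np.float64)
    for bi in range(b):
        for j in range(t_out):
            for l in range(f):
                v = y[bi, j, l] + bias[l]
                out[bi, j, l] = v
                s[l] += np.float64(v)
                sq[l] += np.float64(v) * np.float64(v)
    return s, sq


@njit(cache=True, fastmath=True)
def _bn_fwd(x, mean, invstd, gamma, beta, slope, fuse_act, out):
    m, c = x.shape
    one = np.float32(1.0)
    sel = slope - one  # branchless LeakyReLU: pre * (1 + sel*(pre<0))
    for i in range(m):
        for l in range(c):
            pre = (x[i, l] - mean[l]) * invstd[l] * gamma[l] + beta[l]
            if fuse_act:
                pre *= one + sel * np.float32(pre < 0.0)
            out[i, l] = pre


@njit(cache=True, fastmath=True)
def _bn_bwd_reduce(dy, x, mean, invstd, gamma, beta, slope, fuse_act):
    m, c = dy.shape
    dgamma = np.zeros(c, dtype=np.float32)
    dbeta = np.zeros(c, dtype=np.float32)
    one = np.float32(1.0)
    sel = slope - one
    for i in range(m):
        for l in range(c):
            xhat = (x[i, l] - mean[l]) * invstd[l]
            d = dy[i, l]
            if fuse_act:
                pre = xhat * gamma[l] + beta[l]
                d *= one + sel * np.float32(pre < 0.0)
            dgamma[l] += d * xhat
            dbeta[l] += d
    return dgamma, dbeta


@njit(cache=True, fastmath=True)
def _bn_bwd_dx(dy, x, mean, invstd, gamma, beta, dgamma, dbeta, m_count,
               slope, fuse_act, out):
    m, c = dy.shape
    one = np.float32(1.0)
    sel = slope - one
    for i in range(m):
        for l in range(c):
            xhat = (x[i, l] - mean[l]) * invstd[l]
            d = dy[i, l]
            if fuse_act:
                pre = xhat * gamma[l] + beta[l]
                d *= one + sel * np.float32(pre < 0.0)
            out[i, l] = (
                gamma[l] * invstd[l]
                * (d - dbeta[l] / m_count - xhat * dgamma[l] / m_count)
            )


@njit(cache=True, fastmath=True)
def _bn_bwd_dx_into_g(dy, x, mean, invstd, gamma, beta, dgamma, dbeta,
                      m_count, slope, fuse_act, g, t_out):
    """Like _bn_bwd_dx but scatters rows straight into a conv gradient
    buffer ``g`` of shape (B, t_ph, C) whose valid region is [:, :t_out]."""
    m, c = dy.shape
    one = np.float32(1.0)
    sel = slope - one
    for i in range(m):
        bi = i // t_out
        j = i - bi * t_out
        for l in range(c):
            xhat = (x[i, l] - mean[l]) * invstd[l]
            d = dy[i, l]
            if fuse_act:
                pre = xhat * gamma[l] + beta[l]
                d *= one + sel * np.float32(pre < 0.0)
            g[bi, j, l] = (
                gamma[l] * invstd[l]
                * (d - dbeta[l] / m_count - xhat * dgamma[l] / m_count)
            )


class BatchNorm(Layer):
    """Batch normalization over (batch, time) per channel, channels-last.

    Defaults: momentum 0.9 on the running moments (so the inference
    statistics track training within tens of batches even in short runs),
    eps 1e-3.
    Fresh (identity) running stats make inference a no-op on zero input.
    Optionally fuses a trailing LeakyReLU (``act_slope``) into the same
    memory pass.
    """

    def __init__(
        self,
        n_features: int,
        momentum: float = 0.9,
        eps: float = 1e-3,
        act_slope: float | None = None,
        name: str = "bn",
    ):
        self.gamma = Param(np.ones(n_features), name=f"{name}.gamma")
        self.beta = Param(np.zeros(n_features), name=f"{name}.beta")
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.act_slope = act_slope
        self._cache: tuple | None = None
        self._pool = _BufferPool()
        self._collect: list | None = None

    def begin_collect(self) -> None:
        """Start accumulating exact population statistics (precise BN)."""
        self._collect = [0.0, 0.0, 0]  # sum, sumsq (per channel), count

    def finalize_collect(self) -> None:
        """Replace the running moments with the collected population ones."""
        s, sq, m = self._collect
        if m > 0:
            mean = s / m
            var = np.clip(sq / m - mean**2, 0.0, None)
            self.running_mean = mean.astype(np.float32)
            self.running_var = var.astype(np.float32)
        self._collect = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(
        self, x: np.ndarray, training: bool = True, stats=None
    ) -> np.ndarray:
        """Normalize; ``stats`` may carry precomputed per-channel (sum, sumsq)
        from a fused upstream pass."""
        fuse = self.act_slope is not None
        slope = np.float32(self.act_slope if fuse else 0.0)
        shape = x.shape
        c = shape[-1]
        x2 = x.reshape(-1, c)
        out = self._pool.get("y", x2.shape)
        if not training:
            invstd = (1.0 / np.sqrt(self.running_var + self.eps)).astype(np.float32)
            _bn_fwd(x2, self.running_mean, invstd, self.gamma.data,
                    self.beta.data, slope, fuse, out)
            return out.reshape(shape)
        m = x2.shape[0]
        s, sq = stats if stats is not None else _bn_stats(x2)
        if self._collect is not None:
            self._collect[0] = self._collect[0] + np.asarray(s, dtype=np.float64)
            self._collect[1] = self._collect[1] + np.asarray(sq, dtype=np.float64)
            self._collect[2] += m
        mean = (s / m).astype(np.float32)
        var = (sq / m - (s / m) ** 2).clip(min=0.0).astype(np.float32)
        self.running_mean = (
            self.momentum * self.running_mean + (1 - self.momentum) * mean
        ).astype(np.float32)
        self.running_var = (
            self.momentum * self.running_var + (1 - self.momentum) * var
        ).astype(np.float32)
        invstd = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
        _bn_fwd(x2, mean, invstd, self.gamma.data, self.beta.data, slope, fuse, out)
        self._cache = (x2, mean, invstd, m, shape)
        return out.reshape(shape)

    def backward(self, dy: np.ndarray, into: "Conv1d | None" = None) -> np.ndarray | None:
        """Input gradient; with ``into`` set, rows are written directly to
        that convolution's gradient buffer and None is returned."""
        x2, mean, invstd, m, shape = self._cache
        fuse = self.act_slope is not None
        slope = np.float32(self.act_slope if fuse else 0.0)
        dy2 = dy.reshape(-1, shape[-1])
        dgamma, dbeta = _bn_bwd_reduce(
            dy2, x2, mean, invstd, self.gamma.data, self.beta.data, slope, fuse
        )
        self.gamma.grad += dgamma
        self.beta.grad += dbeta
        if into is not None:
            g, t_out = into.grad_buffer()
            _bn_bwd_dx_into_g(
                dy2, x2, mean, invstd, self.gamma.data, self.beta.data,
                dgamma, dbeta, np.float32(m), slope, fuse, g, t_out,
            )
            return None
        dx = self._pool.get("dx", dy2.shape)
        _bn_bwd_dx(
            dy2, x2, mean, invstd, self.gamma.data, self.beta.data,
            dgamma, dbeta, np.float32(m), slope, fuse, dx,
        )
        return dx.reshape(shape)


@njit(cache=True, fastmath=True)
def _add_lrelu_fwd(a, b, slope, out):
    m, c = a.shape
    one = np.float32(1.0)
    sel = slope - one
    for i in range(m):
        for l in range(c):
            v = a[i, l] + b[i, l]
            v *= one + sel * np.float32(v < 0.0)
            out[i, l] = v


@njit(cache=True, fastmath=True)
def _lrelu_bwd_from_y(dy, y, slope, out):
    m, c = dy.shape
    one = np.float32(1.0)
    sel = slope - one
    for i in range(m):
        for l in range(c):
            out[i, l] = dy[i, l] * (one + sel * np.float32(y[i, l] < 0.0))


class AddLeakyReLU(Layer):
    """Fused residual merge: LeakyReLU(main + shortcut), single memory pass."""

    def __init__(self, slope: float = 0.01):
        self.slope = np.float32(slope)
        self._pool = _BufferPool()
        self._shape: tuple | None = None

    def forward_pair(self, main: np.ndarray, shortcut: np.ndarray) -> np.ndarray:
        self._shape = main.shape
        c = main.shape[-1]
        m2 = np.ascontiguousarray(main).reshape(-1, c)
        s2 = np.ascontiguousarray(shortcut).reshape(-1, c)
        y = self._pool.get("y", m2.shape)
        _add_lrelu_fwd(m2, s2, self.slope, y)
        return y.reshape(self._shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the (shared) pre-activation sum."""
        c = self._shape[-1]
        d = self._pool.get("d", (dy.size // c, c))
        _lrelu_bwd_from_y(dy.reshape(-1, c), self._pool.get("y", (dy.size // c, c)),
                          self.slope, d)
        return d.reshape(self._shape)


class LeakyReLU(Layer):
    """Standalone LeakyReLU for small (2-D) activations."""

    def __init__(self, slope: float = 0.01):
        self.slope = np.float32(slope)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return F.leaky_relu(x, self.slope)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * F.leaky_relu_grad(self._x, self.slope)


class AvgPool1d(Layer):
    """Non-overlapping temporal average pooling, (B, T, C) -> (B, T//p, C)."""

    def __init__(self, pool: int = 2):
        self.pool = pool
        self._in_t = 0
        self._pool_bufs = _BufferPool()

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        b, t, c = x.shape
        self._in_t = t
        o = t // self.pool
        out = self._pool_bufs.get("y", (b, o, c))
        np.mean(
            x[:, : o * self.pool].reshape(b, o, self.pool, c), axis=2, out=out
        )
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, o, c = dy.shape
        dx = self._pool_bufs.get("dx", (b, self._in_t, c))
        dx[:, o * self.pool :] = 0.0
        dx[:, : o * self.pool].reshape(b, o, self.pool, c)[:] = (
            dy / self.pool
        )[:, :, None, :]
        return dx


class SegmentAvgPool(Layer):
    """Average each of ``segments`` near-equal temporal chunks to one vector.

    (B, T, C) -> (B, segments, C): the alternative "global pooling per
    sub-segment" reading of the architecture's pooling stage.
    """

    def __init__(self, segments: int = 8):
        self.segments = segments
        self._edges: np.ndarray | None = None
        self._in_t = 0

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        b, t, c = x.shape
        if t < self.segments:
            raise ValidationError(
                f"sequence of length {t} cannot form {self.segments} segments"
            )
        self._edges = np.linspace(0, t, self.segments + 1).round().astype(int)
        self._in_t = t
        out = np.empty((b, self.segments, c), dtype=x.dtype)
        for i in range(self.segments):
            out[:, i] = x[:, self._edges[i] : self._edges[i + 1]].mean(axis=1)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, c = dy.shape
        dx = np.zeros((b, self._in_t, c), dtype=dy.dtype)
        for i in range(self.segments):
            s, e = self._edges[i], self._edges[i + 1]
            dx[:, s:e] = (dy[:, i] / (e - s))[:, None, :]
        return dx


class Dense(Layer):
    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator | None = None,
        name: str = "dense",
    ):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (d_in + d_out))
        self.W = Param(rng.uniform(-limit, limit, (d_out, d_in)), name=f"{name}.W")
        self.b = Param(np.zeros(d_out), name=f"{name}.b")
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W.data.T + self.b.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += dy.T @ self._x
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.data


# --- indRNN ----------------------------------------------------------------


@dataclass
class IndRNNParams:
    """Functional parameter bundle of one indRNN layer.

    ``W`` maps inputs to hidden pre-activations, ``u`` is the *per-unit*
    recurrent weight (element-wise — no hidden-to-hidden matrix), ``b`` the
    bias. ``|u|`` is kept within ``u_clip`` after every optimizer step.
    """

    W: np.ndarray  # (units, d_in)
    u: np.ndarray  # (units,)
    b: np.ndarray  # (units,)
    u_clip: float = np.inf


def indrnn_step(x, h_prev, params: IndRNNParams, activation=None):
    """One recurrence step: ``act(W x + u * h_prev + b)`` (default act ReLU)."""
    x = np.asarray(x, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    W = np.asarray(params.W, dtype=np.float64)
    if W.shape[1] != x.shape[-1]:
        raise ValidationError(
            f"input dim {x.shape[-1]} does not match W columns {W.shape[1]}"
        )
    if h_prev.shape[-1] != W.shape[0]:
        raise ValidationError(
            f"hidden dim {h_prev.shape[-1]} does not match W rows {W.shape[0]}"
        )
    a = x @ W.T + np.asarray(params.u) * h_prev + np.asarray(params.b)
    if activation is None:
        return np.maximum(a, 0.0)
    return activation(a)


def indrnn_forward(sequence, layer_params: list[IndRNNParams], activation=None):
    """Run stacked indRNN layers over a (T, d) sequence; return last hidden.

    Layer ``l+1`` consumes the full hidden-state sequence of layer ``l``
    (each unit of the next layer sees all units of the previous one).
    """
    seq = np.asarray(sequence, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValidationError("sequence must be a non-empty (T, d) array")
    for params in layer_params:
        units = params.W.shape[0]
        h = np.zeros(units)
        states = []
        for t in range(seq.shape[0]):
            h = indrnn_step(seq[t], h, params, activation)
            states.append(h)
        seq = np.asarray(states)
    return seq[-1]


@njit(cache=True, fastmath=True)
def _indrnn_fwd_kernel(pre, u, h):
    b, t, n = pre.shape
    zero = np.float32(0.0)
    for i in range(b):
        for l in range(n):
            h[i, 0, l] = max(pre[i, 0, l], zero)
    for step in range(1, t):
        for i in range(b):
            for l in range(n):
                a = pre[i, step, l] + u[l] * h[i, step - 1, l]
                h[i, step, l] = max(a, zero)


@njit(cache=True, fastmath=True)
def _indrnn_bwd_kernel(dh, h, u, dpre):
    b, t, n = dh.shape
    du = np.zeros(n, dtype=np.float64)
    carry = np.zeros((b, n), dtype=dh.dtype)
    for step in range(t - 1, -1, -1):
        for i in range(b):
            for l in range(n):
                da = (dh[i, step, l] + carry[i, l]) * np.float32(
                    h[i, step, l] > 0.0
                )
                dpre[i, step, l] = da
                if step > 0:
                    du[l] += np.float64(da * h[i, step - 1, l])
                carry[i, l] = da * u[l]
    return du


class IndRNN(Layer):
    """Batched indRNN layer, (B, T, d_in) -> (B, T, units), ReLU activation.

    The recurrent weight ``u`` is initialized uniform on [-1, 1] and clipped
    to ``|u| <= u_clip`` after every optimizer step; with ``u_clip =
    2**(1/T)`` the memory a unit can accumulate over a T-step sequence stays
    bounded, which is what makes deep stacks trainable.
    """

    def __init__(
        self,
        d_in: int,
        units: int,
        u_clip: float = np.inf,
        rng: np.random.Generator | None = None,
        name: str = "indrnn",
    ):
        rng = rng or np.random.default_rng(0)
        limit = np.sqrt(6.0 / (d_in + units))
        self.W = Param(rng.uniform(-limit, limit, (units, d_in)), name=f"{name}.W")
        self.u = Param(
            np.clip(rng.uniform(-1.0, 1.0, units), -u_clip, u_clip),
            name=f"{name}.u",
            clip_abs=float(u_clip) if np.isfinite(u_clip) else None,
        )
        self.b = Param(np.zeros(units), name=f"{name}.b")
        self.d_in, self.units = d_in, units
        self._cache: tuple | None = None
        self._pool = _BufferPool()

    def params(self) -> list[Param]:
        return [self.W, self.u, self.b]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] < 1:
            raise ValidationError("IndRNN expects a non-empty (B, T, d) input")
        b, t, d = x.shape
        pre = self._pool.get("pre", (b, t, self.units))
        np.matmul(x.reshape(b * t, d), self.W.data.T,
                  out=pre.reshape(b * t, self.units))
        pre += self.b.data
        h = self._pool.get("h", (b, t, self.units))
        _indrnn_fwd_kernel(pre, self.u.data, h)
        self._cache = (x, h)
        return h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, h = self._cache
        b, t, d = x.shape
        dpre = self._pool.get("dpre", (b, t, self.units))
        du = _indrnn_bwd_kernel(np.ascontiguousarray(dy), h, self.u.data, dpre)
        self.u.grad += du.astype(np.float32)
        flat = dpre.reshape(b * t, self.units)
        self.W.grad += flat.T @ x.reshape(b * t, d)
        self.b.grad += _colsum(flat)
        dx = self._pool.get("dx", (b, t, d))
        np.matmul(flat, self.W.data, out=dx.reshape(b * t, d))
        return dx
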