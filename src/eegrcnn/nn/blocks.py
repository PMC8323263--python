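"""Residual 1-D convolution blocks (channels-last feature maps).

Each block runs three same-padded convolutions (kernels 8/5/3 by default,
the middle one at stride 2) with batch norm after each and LeakyReLU after
the first two; the input joins the main path through a shortcut before the
final LeakyReLU. The shortcut is a kernel-1 stride-2 projection (+BN)
whenever the block declares one *or* the channel count changes — an add
could not type-check otherwise — and plain stride-2 subsampling when the
channels already match. Output time length is ``ceil(T/2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..exceptions import ValidationError
from .layers import AddLeakyReLU, BatchNorm, Conv1d, Layer, Param


@dataclass
class BlockSpec:
    """Declarative description of one residual block."""

    filters: int
    kernels: tuple[int, int, int] = (8, 5, 3)
    strides: tuple[int, int, int] = (1, 2, 1)
    projection_shortcut: bool = True

    def __post_init__(self) -> None:
        if self.filters < 1:
            raise ValidationError("filters must be >= 1")
        if any(k < 1 for k in self.kernels):
            raise ValidationError("kernels must be positive")


class ResidualBlock1d(Layer):
    def __init__(
        self,
        c_in: int,
        spec: BlockSpec,
        leaky_slope: float = 0.01,
        bn_momentum: float = 0.9,
        bn_eps: float = 1e-3,
        rng: np.random.Generator | None = None,
        need_input_grad: bool = True,
        name: str = "block",
    ):
        rng = rng or np.random.default_rng(0)
        f = spec.filters
        k1, k2, k3 = spec.kernels
        s1, s2, s3 = spec.strides
        self.spec = spec
        self.c_in = c_in
        self.total_stride = s1 * s2 * s3
        bn = dict(momentum=bn_momentum, eps=bn_eps)
        self.conv1 = Conv1d(c_in, f, k1, s1, rng, need_input_grad, f"{name}.conv1")
        self.bn1 = BatchNorm(f, **bn, act_slope=leaky_slope, name=f"{name}.bn1")
        self.conv2 = Conv1d(f, f, k2, s2, rng, True, f"{name}.conv2")
        self.bn2 = BatchNorm(f, **bn, act_slope=leaky_slope, name=f"{name}.bn2")
        self.conv3 = Conv1d(f, f, k3, s3, rng, True, f"{name}.conv3")
        self.bn3 = BatchNorm(f, **bn, name=f"{name}.bn3")
        self.merge = AddLeakyReLU(leaky_slope)
        # A projection is structurally required when channels change.
        self.has_projection = spec.projection_shortcut or c_in != f
        if self.has_projection:
            self.conv_sc = Conv1d(
                c_in, f, 1, self.total_stride, rng, need_input_grad, f"{name}.proj"
            )
            self.bn_sc = BatchNorm(f, **bn, name=f"{name}.proj_bn")
        self._x_shape: tuple | None = None

    def params(self) -> list[Param]:
        out = []
        for lyr in self._layers():
            out.extend(lyr.params())
        return out

    def _layers(self) -> list[Layer]:
        layers = [self.conv1, self.bn1, self.conv2, self.bn2, self.conv3, self.bn3]
        if self.has_projection:
            layers += [self.conv_sc, self.bn_sc]
        return layers

    @staticmethod
    def _fwd_pair(conv, bn, x, training):
        h = conv.forward(x, training)
        return bn.forward(h, training, stats=conv.last_stats)

    @staticmethod
    def _bwd_pair(bn, conv, d):
        if conv.supports_grad_into:
            bn.backward(d, into=conv)
            return conv.backward(None)
        return conv.backward(bn.backward(d))

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        self._x_shape = x.shape
        m = self._fwd_pair(self.conv1, self.bn1, x, training)
        m = self._fwd_pair(self.conv2, self.bn2, m, training)
        m = self._fwd_pair(self.conv3, self.bn3, m, training)
        if self.has_projection:
            sc = self._fwd_pair(self.conv_sc, self.bn_sc, x, training)
        else:
            sc = x[:, :: self.total_stride, :]
        if m.shape != sc.shape:  # structurally impossible; guards refactors
            raise AssertionError(
                f"residual add shape mismatch: main {m.shape} vs shortcut {sc.shape}"
            )
        return self.merge.forward_pair(m, sc)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.merge.backward(dy)
        dm = self._bwd_pair(self.bn3, self.conv3, d)
        dm = self._bwd_pair(self.bn2, self.conv2, dm)
        dx = self._bwd_pair(self.bn1, self.conv1, dm)
        if self.has_projection:
            dx = dx + self._bwd_pair(self.bn_sc, self.conv_sc, d)
        else:
            dsc = np.zeros(self._x_shape, dtype=dy.dtype)
            dsc[:, :: self.total_stride, :] = d
            dx = dx + dsc
        return dx

    def param_count(self, include_bn: bool = True) -> int:
        """Closed-form weight+bias count (optionally excluding batch norm)."""
        layers = [self.conv1, self.conv2, self.conv3]
        if self.has_projection:
            layers.append(self.conv_sc)
        n = sum(p.size for lyr in layers for p in lyr.params())
        if include_bn:
            bns = [self.bn1, self.bn2, self.bn3]
            if self.has_projection:
                bns.append(self.bn_sc)
            n += sum(p.size for lyr in bns for p in lyr.params())
        return n


def residual_block_forward(
    feature_map: np.ndarray, block: ResidualBlock1d, training: bool = False
) -> np.ndarray:
    """Functional wrapper: run one block on a (B, T, C) feature map."""
    return block.forward(np.ascontiguousarray(feature_map, dtype=np.float32), training)
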