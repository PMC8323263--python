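"""The full RCNN: residual 1-D CNN front end + stacked indRNN + softmax head.

The default architecture mirrors the published layer table: three residual
blocks (64, 128, 64 filters; kernels 8/5/3; one stride-2 stage per block;
kernel-1 projection shortcuts on the first two blocks, and on the third one
a projection is inserted anyway because the channel count changes 128→64),
temporal average pooling, two 128-unit indRNN layers each followed by batch
norm, a 256-unit fully connected layer and a softmax classifier.

The pooling row of the published table is ambiguous (a global average pool
would leave the recurrent layers a single step to recur over); the default
reading here is average pooling with pool size 2 over time (``pool='avg2'``).
The alternative reading — global average pooling per temporal sub-segment,
recurrence over sub-segment features — is available as ``pool='global'``
with a configurable sub-segment count.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from ..exceptions import DataError, ValidationError
from . import functional as F
from .blocks import BlockSpec, ResidualBlock1d
from .layers import AvgPool1d, BatchNorm, Dense, IndRNN, LeakyReLU, Param, SegmentAvgPool

#: Shortest input that survives three stride-2 stages plus pooling.
MIN_INPUT_LEN = 16


def default_blocks() -> list[BlockSpec]:
    return [
        BlockSpec(64, projection_shortcut=True),
        BlockSpec(128, projection_shortcut=True),
        BlockSpec(64, projection_shortcut=False),
    ]


@dataclass
class ArchitectureSpec:
    """Declarative, serializable description of the network."""

    blocks: list[BlockSpec] = field(default_factory=default_blocks)
    pool: str = "avg2"  # 'avg2' or 'global'
    pool_segments: int = 16  # only used when pool == 'global'
    rnn_layers: list[int] = field(default_factory=lambda: [128, 128])
    dense_units: int = 256
    n_class: int = 2
    leaky_slope: float = 0.01
    bn_momentum: float = 0.9
    bn_eps: float = 1e-3

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValidationError("architecture needs at least one block")
        if any(u < 1 for u in self.rnn_layers):
            raise ValidationError("recurrent units must be positive")
        if self.n_class < 2:
            raise ValidationError("n_class must be >= 2")
        if self.pool not in ("avg2", "global"):
            raise ValidationError(f"unknown pool mode {self.pool!r}")
        self.blocks = [
            b if isinstance(b, BlockSpec) else BlockSpec(**b) for b in self.blocks
        ]

    def to_dict(self) -> dict:
        d = asdict(self)
        for b in d["blocks"]:
            b["kernels"] = list(b["kernels"])
            b["strides"] = list(b["strides"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["blocks"] = [
            BlockSpec(
                filters=b["filters"],
                kernels=tuple(b.get("kernels", (8, 5, 3))),
                strides=tuple(b.get("strides", (1, 2, 1))),
                projection_shortcut=b.get("projection_shortcut", True),
            )
            for b in d["blocks"]
        ]
        return cls(**d)


def reduced_architecture(n_class: int = 3, filters=(16, 32, 16)) -> ArchitectureSpec:
    """Desk-scale variant: same topology, fewer filters per block."""
    f1, f2, f3 = filters
    return ArchitectureSpec(
        blocks=[
            BlockSpec(f1, projection_shortcut=True),
            BlockSpec(f2, projection_shortcut=True),
            BlockSpec(f3, projection_shortcut=False),
        ],
        n_class=n_class,
    )


class RCNNetwork:
    """Buildable, inspectable network handle.

    Exposes the ordered stage list, per-stage output shapes, the total
    trainable parameter count, forward/backward passes and (de)serialization.
    """

    def __init__(self, spec: ArchitectureSpec, input_len: int, seed: int = 0):
        if input_len < MIN_INPUT_LEN:
            raise DataError(
                f"input_len={input_len} too short; minimum is {MIN_INPUT_LEN}"
            )
        self.spec = spec
        self.input_len = input_len
        self.seed = seed
        rng = np.random.default_rng(seed)

        self.blocks: list[ResidualBlock1d] = []
        c = 1
        t = input_len
        self.stage_shapes: list[tuple[str, tuple]] = [("input", (input_len, 1))]
        for i, bspec in enumerate(spec.blocks):
            blk = ResidualBlock1d(
                c,
                bspec,
                leaky_slope=spec.leaky_slope,
                bn_momentum=spec.bn_momentum,
                bn_eps=spec.bn_eps,
                rng=rng,
                need_input_grad=(i > 0),
                name=f"block{i + 1}",
            )
            self.blocks.append(blk)
            c = bspec.filters
            t = F.conv_out_len(t, blk.total_stride)
            self.stage_shapes.append((f"block{i + 1}", (t, c)))

        if spec.pool == "avg2":
            self.pool = AvgPool1d(2)
            t = t // 2
        else:
            self.pool = SegmentAvgPool(spec.pool_segments)
            t = spec.pool_segments
        if t < 1:
            raise DataError(
                f"input_len={input_len} too short for the pooling stage"
            )
        self.seq_len = t
        self.stage_shapes.append((f"pool[{spec.pool}]", (t, c)))

        #: recurrent-weight bound: 2**(1/T) for a T-step pooled sequence
        self.u_clip = float(2.0 ** (1.0 / max(t, 1)))
        self.rnns: list[IndRNN] = []
        self.rnn_bns: list[BatchNorm] = []
        d = c
        for j, units in enumerate(spec.rnn_layers):
            self.rnns.append(
                IndRNN(d, units, u_clip=self.u_clip, rng=rng, name=f"indrnn{j + 1}")
            )
            self.rnn_bns.append(
                BatchNorm(
                    units, momentum=spec.bn_momentum, eps=spec.bn_eps,
                    name=f"indrnn{j + 1}_bn",
                )
            )
            d = units
            self.stage_shapes.append((f"indrnn{j + 1}+bn", (t, units)))

        self.dense = Dense(d, spec.dense_units, rng, name="dense")
        self.dense_act = LeakyReLU(spec.leaky_slope)
        self.head = Dense(spec.dense_units, spec.n_class, rng, name="softmax")
        self.stage_shapes.append(("dense", (spec.dense_units,)))
        self.stage_shapes.append(("softmax", (spec.n_class,)))
        self._last_rnn_shape: tuple | None = None

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 2 or x.shape[1] != self.input_len:
            raise ValidationError(
                f"expected (batch, {self.input_len}) input, got {x.shape}"
            )
        h = np.ascontiguousarray(x[:, :, None])  # (B, T, 1) channels-last
        for blk in self.blocks:
            h = blk.forward(h, training)
        h = self.pool.forward(h, training)
        for rnn, bn in zip(self.rnns, self.rnn_bns):
            h = bn.forward(rnn.forward(h, training), training)
        self._last_rnn_shape = h.shape
        last = h[:, -1, :]
        z = self.dense_act.forward(self.dense.forward(last, training))
        return self.head.forward(z, training)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities in inference mode (running BN statistics)."""
        return F.softmax(self.forward_logits(x, training=False))

    def predict_window(self, window: np.ndarray) -> np.ndarray:
        """Probability vector for a single window (softmax over classes)."""
        window = np.asarray(window, dtype=np.float32).ravel()
        if window.size != self.input_len:
            raise ValidationError(
                f"window has {window.size} samples, model expects {self.input_len}"
            )
        return self.predict_proba(window[None, :])[0]

    def loss_and_backward(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy on a batch, with gradients accumulated."""
        logits = self.forward_logits(x, training=True)
        probs = F.softmax(logits)
        loss = F.cross_entropy(probs, y)
        b = x.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(b), y] -= 1.0
        dlogits /= b
        self._backward(dlogits.astype(np.float32))
        return loss

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.dense.backward(self.dense_act.backward(d))
        dh = np.zeros(self._last_rnn_shape, dtype=np.float32)
        dh[:, -1, :] = d
        for rnn, bn in zip(reversed(self.rnns), reversed(self.rnn_bns)):
            dh = rnn.backward(bn.backward(dh))
        dh = self.pool.backward(dh)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)

    def recalibrate_bn(self, x: np.ndarray, batch_size: int = 64) -> None:
        """Precise batch norm: set the inference statistics to the exact
        population moments of each normalized layer input over ``x``.

        The exponential running average collected during short trainings is
        a poor population estimate; one post-training pass (training-mode
        normalization, no parameter updates) computes it exactly.
        """
        x = np.asarray(x, dtype=np.float32)
        bns = self._all_bns()
        for bn in bns:
            bn.begin_collect()
        for start in range(0, x.shape[0], batch_size):
            self.forward_logits(x[start : start + batch_size], training=True)
        for bn in bns:
            bn.finalize_collect()

    # -- introspection ------------------------------------------------------

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for blk in self.blocks:
            out.extend(blk.params())
        for rnn, bn in zip(self.rnns, self.rnn_bns):
            out.extend(rnn.params())
            out.extend(bn.params())
        out.extend(self.dense.params())
        out.extend(self.head.params())
        return out

    def count_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def max_abs_recurrent_weight(self) -> float:
        return max(float(np.abs(r.u.data).max()) for r in self.rnns)

    def summary(self) -> str:
        """Plain-text layer table (stage, output shape, parameter count)."""
        buf = _io.StringIO()
        buf.write(f"{'stage':<16}{'output shape':<20}{'params':>10}\n")
        buf.write("-" * 46 + "\n")
        per_stage: dict[str, int] = {}
        for i, blk in enumerate(self.blocks):
            per_stage[f"block{i + 1}"] = sum(p.size for p in blk.params())
        for j, (rnn, bn) in enumerate(zip(self.rnns, self.rnn_bns)):
            per_stage[f"indrnn{j + 1}+bn"] = sum(
                p.size for p in rnn.params() + bn.params()
            )
        per_stage["dense"] = sum(p.size for p in self.dense.params())
        per_stage["softmax"] = sum(p.size for p in self.head.params())
        for name, shape in self.stage_shapes:
            n = per_stage.get(name, 0)
            buf.write(f"{name:<16}{str(shape):<20}{n:>10}\n")
        buf.write("-" * 46 + "\n")
        buf.write(f"{'total':<36}{self.count_params():>10}\n")
        buf.write(f"recurrent weight bound u_clip = {self.u_clip:.6f}\n")
        return buf.getvalue()

    # -- persistence --------------------------------------------------------

    def save(self, path, **extra) -> None:
        """Persist spec + parameters (+ any extra arrays, e.g. class names)."""
        arrays = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._all_bns()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        np.savez(
            path,
            spec=json.dumps(self.spec.to_dict()),
            input_len=self.input_len,
            seed=self.seed,
            **arrays,
            **extra,
        )

    def _all_bns(self) -> list[BatchNorm]:
        bns: list[BatchNorm] = []
        for blk in self.blocks:
            bns += [blk.bn1, blk.bn2, blk.bn3]
            if blk.has_projection:
                bns.append(blk.bn_sc)
        bns += self.rnn_bns
        return bns

    @classmethod
    def load(cls, path) -> "RCNNetwork":
        try:
            with np.load(path, allow_pickle=False) as data:
                spec = ArchitectureSpec.from_dict(json.loads(str(data["spec"])))
                net = cls(spec, int(data["input_len"]), seed=int(data["seed"]))
                for i, p in enumerate(net.parameters()):
                    p.data[...] = data[f"p{i}"]
                for i, bn in enumerate(net._all_bns()):
                    bn.running_mean[...] = data[f"rm{i}"]
                    bn.running_var[...] = data[f"rv{i}"]
        except (OSError, KeyError) as exc:
            raise DataError(f"cannot load model from {path}: {exc}") from exc
        return net


def build_rcnn(spec: ArchitectureSpec, input_len: int, seed: int = 0) -> RCNNetwork:
    """Build the full network for windows of ``input_len`` samples."""
    return RCNNetwork(spec, input_len, seed=seed)
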