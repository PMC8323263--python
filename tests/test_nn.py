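"""Layer-level numerics: indRNN recurrence, convolution, batch norm, blocks."""

import numpy as np
import pytest
from scipy import signal as sps

from eegrcnn.exceptions import ValidationError
from eegrcnn.nn import (
    BlockSpec,
    IndRNNParams,
    ResidualBlock1d,
    indrnn_forward,
    indrnn_step,
    residual_block_forward,
)
from eegrcnn.nn.layers import BatchNorm, Conv1d, IndRNN
from eegrcnn.nn.functional import leaky_relu, softmax


def scalar_indrnn_oracle(seq, layer_params):
    """Brute-force per-scalar unrolled recurrence (float64 loops)."""
    seq = [list(map(float, row)) for row in seq]
    for params in layer_params:
        units, d = params.W.shape
        h = [0.0] * units
        states = []
        for x in seq:
            nxt = []
            for u_i in range(units):
                a = sum(params.W[u_i, j] * x[j] for j in range(d))
                a += params.u[u_i] * h[u_i] + params.b[u_i]
                nxt.append(a if a > 0 else 0.0)
            h = nxt
            states.append(h)
        seq = states
    return np.asarray(seq[-1])


def random_params(rng, d, units):
    return IndRNNParams(
        W=rng.standard_normal((units, d)) * 0.5,
        u=rng.uniform(-1, 1, units),
        b=rng.standard_normal(units) * 0.1,
    )


class TestIndRNNStep:
    def test_identity_weights_relu(self):
        p = IndRNNParams(W=np.eye(2), u=np.zeros(2), b=np.zeros(2))
        h = indrnn_step([1.0, -2.0], [0.0, 0.0], p)
        assert h.tolist() == [1.0, 0.0]

    def test_pure_memory(self):
        p = IndRNNParams(W=np.zeros((1, 1)), u=np.ones(1), b=np.zeros(1))
        assert indrnn_step([0.0], [3.0], p).tolist() == [3.0]

    def test_dimension_mismatch(self):
        p = IndRNNParams(W=np.zeros((2, 3)), u=np.zeros(2), b=np.zeros(2))
        with pytest.raises(ValidationError):
            indrnn_step([1.0, 2.0], [0.0, 0.0], p)
        with pytest.raises(ValidationError):
            indrnn_step([1.0, 2.0, 3.0], [0.0], p)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(0)
        p = random_params(rng, 3, 4)
        seq = rng.standard_normal((5, 3))
        got = indrnn_forward(seq, [p])
        want = scalar_indrnn_oracle(seq, [p])
        np.testing.assert_allclose(got, want, atol=1e-10)


class TestIndRNNLayer:
    def test_length_one_equals_single_step(self):
        rng = np.random.default_rng(1)
        p1, p2 = random_params(rng, 3, 4), random_params(rng, 4, 4)
        x = rng.standard_normal((1, 3))
        got = indrnn_forward(x, [p1, p2])
        h1 = indrnn_step(x[0], np.zeros(4), p1)
        want = indrnn_step(h1, np.zeros(4), p2)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_zero_recurrence_ignores_order_of_past_inputs(self):
        rng = np.random.default_rng(2)
        p = random_params(rng, 3, 4)
        p.u[:] = 0.0
        seq = rng.standard_normal((6, 3))
        base = indrnn_forward(seq, [p])
        perm = seq.copy()
        perm[:5] = perm[:5][::-1]
        np.testing.assert_allclose(indrnn_forward(perm, [p]), base, atol=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            indrnn_forward(np.zeros((0, 3)), [random_params(np.random.default_rng(0), 3, 2)])

    def test_batched_layer_matches_oracle(self):
        """Production (numba, float32) stacked layers vs scalar oracle."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            d, units, t = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 9)
            l1 = IndRNN(int(d), int(units), rng=rng)
            l2 = IndRNN(int(units), int(units), rng=rng)
            x = rng.standard_normal((2, int(t), int(d))).astype(np.float32)
            h = l2.forward(l1.forward(x, True), True)
            for bi in range(2):
                want = scalar_indrnn_oracle(
                    x[bi].astype(np.float64),
                    [
                        IndRNNParams(l.W.data.astype(float), l.u.data.astype(float),
                                     l.b.data.astype(float))
                        for l in (l1, l2)
                    ],
                )
                np.testing.assert_allclose(h[bi, -1], want, atol=1e-5)


class TestConv1d:
    @pytest.mark.parametrize("kernel,stride", [(8, 1), (5, 2), (3, 1), (1, 2)])
    def test_matches_direct_convolution(self, kernel, stride):
        rng = np.random.default_rng(4)
        conv = Conv1d(3, 5, kernel, stride, rng)
        x = rng.standard_normal((2, 23, 3)).astype(np.float32)
        y = conv.forward(x, True)
        t = x.shape[1]
        out = -(-t // stride)
        assert y.shape == (2, out, 5)
        pad = max((out - 1) * stride + kernel - t, 0)
        left = pad // 2
        xp = np.pad(np.asarray(x, dtype=np.float64), ((0, 0), (left, pad - left), (0, 0)))
        for b in range(2):
            for ti in range(out):
                for f in range(5):
                    want = sum(
                        xp[b, ti * stride + j] @ conv.W.data[j, :, f].astype(float)
                        for j in range(kernel)
                    ) + conv.b.data[f]
                    assert y[b, ti, f] == pytest.approx(want, abs=1e-4)

    def test_output_length_is_ceil(self):
        conv = Conv1d(1, 2, 5, 2, np.random.default_rng(0), need_input_grad=True)
        y = conv.forward(np.zeros((1, 11, 1), dtype=np.float32), True)
        assert y.shape[1] == 6  # ceil(11/2)

    def test_channel_mismatch_rejected(self):
        conv = Conv1d(3, 4, 3, 1)
        with pytest.raises(ValidationError):
            conv.forward(np.zeros((1, 10, 2), dtype=np.float32), True)


class TestBatchNorm:
    def test_training_normalizes_batch(self):
        rng = np.random.default_rng(5)
        bn = BatchNorm(4)
        x = (rng.standard_normal((8, 50, 4)) * 3 + 7).astype(np.float32)
        y = bn.forward(x, training=True)
        flat = y.reshape(-1, 4)
        np.testing.assert_allclose(flat.mean(0), 0.0, atol=1e-3)
        np.testing.assert_allclose(flat.std(0), 1.0, atol=2e-2)

    def test_inference_identity_stats_passthrough_on_zero(self):
        bn = BatchNorm(3)
        x = np.zeros((2, 10, 3), dtype=np.float32)
        np.testing.assert_array_equal(bn.forward(x, training=False), x)

    def test_running_stats_converge(self):
        rng = np.random.default_rng(6)
        bn = BatchNorm(2, momentum=0.9)
        for _ in range(100):
            bn.forward((rng.standard_normal((16, 20, 2)) * 2 + 5).astype(np.float32),
                       training=True)
        np.testing.assert_allclose(bn.running_mean, 5.0, atol=0.2)
        np.testing.assert_allclose(bn.running_var, 4.0, rtol=0.15)


class TestActivations:
    def test_leaky_relu_pointwise(self):
        x = np.array([-2.0, -0.5, 0.0, 0.5, 2.0], dtype=np.float32)
        y = leaky_relu(x, np.float32(0.01))
        np.testing.assert_allclose(y, [-0.02, -0.005, 0.0, 0.5, 2.0], atol=1e-7)

    def test_softmax_rows_sum_to_one(self):
        z = np.random.default_rng(7).standard_normal((5, 4)) * 10
        p = softmax(z)
        np.testing.assert_allclose(p.sum(1), 1.0, atol=1e-6)
        assert (p >= 0).all()


class TestResidualBlock:
    def test_halves_time_length(self):
        rng = np.random.default_rng(8)
        blk = ResidualBlock1d(1, BlockSpec(4), rng=rng)
        for t in (4096, 101, 57):
            y = residual_block_forward(rng.standard_normal((1, t, 1)), blk, True)
            assert y.shape == (1, -(-t // 2), 4)

    def test_zero_input_zero_output_inference(self):
        # fresh BN has identity running stats; LeakyReLU(0) = 0
        blk = ResidualBlock1d(2, BlockSpec(3), rng=np.random.default_rng(9))
        y = residual_block_forward(np.zeros((1, 32, 2)), blk, training=False)
        np.testing.assert_allclose(y, 0.0, atol=1e-6)

    def test_projection_forced_when_channels_change(self):
        blk = ResidualBlock1d(
            8, BlockSpec(4, projection_shortcut=False), rng=np.random.default_rng(10)
        )
        assert blk.has_projection  # 8 -> 4 channels cannot add without one

    def test_subsample_shortcut_when_channels_match(self):
        blk = ResidualBlock1d(
            4, BlockSpec(4, projection_shortcut=False), rng=np.random.default_rng(11)
        )
        assert not blk.has_projection

    def test_block1_parameter_count_closed_form(self):
        """Conv weights+biases of the first block (64 filters, 1 input
        channel, kernels 8/5/3 plus the kernel-1 projection): 33,600."""
        blk = ResidualBlock1d(1, BlockSpec(64), rng=np.random.default_rng(12))
        want = (1 * 8 * 64 + 64) + (64 * 5 * 64 + 64) + (64 * 3 * 64 + 64) + (1 * 1 * 64 + 64)
        assert want == 33600
        assert blk.param_count(include_bn=False) == 33600
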