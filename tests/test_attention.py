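"""IB-MSA: biased logits, softmax attention, initialization, oracle checks."""

import numpy as np
import pytest

from vesselseg.attention import (AttentionParams, WindowAttention,
                                 absolute_position_embedding, ib_attention,
                                 ib_logits, init_inductive_bias,
                                 zero_positional_params)
from vesselseg.nn import Tensor
from vesselseg.windowing import (TokenGrid, build_attention_mask,
                                 build_relative_index, cyclic_shift,
                                 partition_windows, reverse_windows)


def naive_softmax_attention(q, k, v):
    """Independent reference: plain scaled-dot-product attention."""
    d = q.shape[-1]
    logits = q @ k.T / np.sqrt(d)
    w = np.exp(logits - logits.max(-1, keepdims=True))
    w /= w.sum(-1, keepdims=True)
    return w @ v


def random_params(rng, heads, d, window, dtype=np.float64):
    p = zero_positional_params(heads, d, window, dtype=dtype)
    p.bias_table.data = rng.normal(0, 0.5, p.bias_table.shape)
    for r in p.r_axial:
        r.data = rng.normal(0, 0.3, r.shape)
    return p


class TestLogits:
    def test_zero_bias_reduces_to_scaled_dot_product(self, rng):
        d, window = 4, (2, 2, 2)
        q, k = rng.normal(size=(8, d)), rng.normal(size=(8, d))
        params = zero_positional_params(1, d, window, dtype=np.float64)
        tab = build_relative_index(window)
        out = ib_logits(Tensor(q), Tensor(k), params, tab)
        assert np.allclose(out.data, q @ k.T / np.sqrt(d), atol=1e-12)

    def test_single_token_window(self, rng):
        """P=1: logit is q·k/sqrt(d) plus the zero-offset bias entry (the
        axial terms vanish at zero offset under the inductive-bias init)."""
        d = 3
        q, k = rng.normal(size=(1, d)), rng.normal(size=(1, d))
        params = init_inductive_bias(1, d, (1, 1, 1), dtype=np.float64)
        params.bias_table.data[:] = rng.normal(size=params.bias_table.shape)
        tab = build_relative_index((1, 1, 1))
        out = ib_logits(Tensor(q), Tensor(k), params, tab)
        expected = (q @ k.T).item() / np.sqrt(d) + float(params.bias_table.data[0, 0])
        assert np.allclose(out.data, expected)

    def test_hand_arithmetic_two_tokens(self):
        """P=2 along one axis, d=1: evaluate the biased logit by hand.

        l_ij = (q_i/sqrt(d)) * (k_j + rW + rH + rD at the pair offset)
               + table[rel(i,j)].
        """
        window = (2, 1, 1)
        tab = build_relative_index(window)
        q = np.array([[2.0], [3.0]])
        k = np.array([[1.0], [-1.0]])
        params = zero_positional_params(1, 1, window, dtype=np.float64)
        # offsets along the first axis: -1, 0, +1 -> rW rows 0, 1, 2
        params.r_axial[0].data[0] = [[0.5], [0.0], [-0.25]]
        params.bias_table.data[:] = np.arange(3)[:, None] * 0.1  # entries .0 .1 .2
        out = ib_logits(Tensor(q), Tensor(k), params, tab).data
        # token coords 0 and 1 on axis 0; rel index for (0,1) -> offset +1
        expected = np.array([
            [2 * (1 + 0.0) + 0.1, 2 * (-1 - 0.25) + 0.2],
            [3 * (1 + 0.5) + 0.0, 3 * (-1 + 0.0) + 0.1],
        ])
        assert np.allclose(out, expected, atol=1e-12)

    def test_finite_for_finite_inputs(self, rng):
        params = random_params(rng, 2, 4, (2, 2, 2))
        tab = build_relative_index((2, 2, 2))
        q = rng.normal(size=(5, 2, 8, 4))
        out = ib_logits(Tensor(q), Tensor(rng.normal(size=(5, 2, 8, 4))), params, tab)
        assert np.isfinite(out.data).all()


class TestAttention:
    def test_uniform_logits_average_values(self, rng):
        d, window = 2, (2, 2, 2)
        v = rng.normal(size=(8, d))
        q = np.zeros((8, d))
        k = rng.normal(size=(8, d))
        params = zero_positional_params(1, d, window, dtype=np.float64)
        out = ib_attention(Tensor(q), Tensor(k), Tensor(v), params,
                           build_relative_index(window))
        assert np.allclose(out.data, v.mean(0), atol=1e-12)

    def test_dominant_logit_selects_value_row(self, rng):
        d, window = 2, (2, 2, 2)
        k = np.zeros((8, d))
        k[3] = 100.0
        q = np.ones((8, d))
        v = rng.normal(size=(8, d))
        params = zero_positional_params(1, d, window, dtype=np.float64)
        out = ib_attention(Tensor(q), Tensor(k), Tensor(v), params,
                           build_relative_index(window))
        assert np.allclose(out.data, v[3], atol=1e-6)

    def test_matches_naive_oracle_with_zero_bias(self, rng):
        d, window = 4, (2, 2, 2)
        q, k, v = (rng.normal(size=(8, d)) for _ in range(3))
        params = zero_positional_params(1, d, window, dtype=np.float64)
        out = ib_attention(Tensor(q), Tensor(k), Tensor(v), params,
                           build_relative_index(window))
        assert np.abs(out.data - naive_softmax_attention(q, k, v)).max() < 1e-6

    def test_rows_sum_to_one_under_mask(self, rng):
        """Softmax normalization holds per window/head with a shifted mask."""
        window, d, heads = (2, 2, 2), 4, 2
        params = random_params(rng, heads, d, window)
        tab = build_relative_index(window)
        mask = build_attention_mask((4, 4, 4), window, (1, 1, 1))
        q = Tensor(rng.normal(size=(8, heads, 8, d)))
        logits = ib_logits(q, Tensor(rng.normal(size=(8, heads, 8, d))), params, tab)
        logits = logits + Tensor(mask[:, None])
        attn = logits.softmax(axis=-1)
        assert np.allclose(attn.data.sum(-1), 1.0, atol=1e-6)
        # blocked pairs carry (numerically) zero attention
        blocked = np.broadcast_to(mask[:, None] < 0, attn.shape)
        assert attn.data[blocked].max() < 1e-12

    def test_fully_blocked_row_raises(self, rng):
        window = (2, 1, 1)
        params = zero_positional_params(1, 1, window, dtype=np.float64)
        mask = np.full((1, 2, 2), -1e9)
        with pytest.raises(ValueError):
            ib_attention(Tensor(rng.normal(size=(2, 1))),
                         Tensor(rng.normal(size=(2, 1))),
                         Tensor(rng.normal(size=(2, 1))),
                         params, build_relative_index(window), mask)


class TestShiftedOracle:
    def test_masked_batched_attention_equals_geometric_windows(self, rng):
        """Cyclic shift + mask on 8 batched windows reproduces brute-force
        attention over the 27 physical windows of the shifted partition."""
        shape, window, shift = (8, 8, 8), (4, 4, 4), (2, 2, 2)
        d = 4
        params = random_params(rng, 1, d, window)
        tab = build_relative_index(window)
        q, k, v = (rng.normal(size=shape + (d,)) for _ in range(3))

        # production path: roll, partition, masked attention, reverse, unroll
        def run(arr):
            return partition_windows(cyclic_shift(TokenGrid(arr), shift),
                                     window, shift).windows.data
        qw, kw, vw = (run(a)[:, None] for a in (q, k, v))  # (8, 1, 64, d)
        mask = build_attention_mask(shape, window, shift)
        out_w = ib_attention(Tensor(qw), Tensor(kw), Tensor(vw), params, tab, mask)
        ws = partition_windows(cyclic_shift(TokenGrid(q), shift), window, shift)
        ws.windows = out_w
        out = cyclic_shift(reverse_windows(ws), shift, inverse=True).tokens.data

        # oracle: per-geometric-window attention with true spatial offsets
        bounds = [0, shift[0], window[0] + shift[0], shape[0]]
        expected = np.empty_like(out)
        rw, rh, rd = (r.data[0] for r in params.r_axial)
        table = params.bias_table.data[:, 0]
        n1, n2 = 2 * window[1] - 1, 2 * window[2] - 1
        for x0, x1 in zip(bounds, bounds[1:]):
            for y0, y1 in zip(bounds, bounds[1:]):
                for z0, z1 in zip(bounds, bounds[1:]):
                    coords = np.stack(np.meshgrid(np.arange(x0, x1),
                                                  np.arange(y0, y1),
                                                  np.arange(z0, z1),
                                                  indexing="ij"), -1).reshape(-1, 3)
                    qi = q[coords[:, 0], coords[:, 1], coords[:, 2]] / np.sqrt(d)
                    ki = k[coords[:, 0], coords[:, 1], coords[:, 2]]
                    vi = v[coords[:, 0], coords[:, 1], coords[:, 2]]
                    off = coords[None, :, :] - coords[:, None, :]
                    kb = (ki[None] + rw[off[..., 0] + window[0] - 1]
                          + rh[off[..., 1] + window[1] - 1]
                          + rd[off[..., 2] + window[2] - 1])
                    logits = np.einsum("id,ijd->ij", qi, kb)
                    flat = ((off[..., 0] + window[0] - 1) * n1
                            + (off[..., 1] + window[1] - 1)) * n2 \
                        + (off[..., 2] + window[2] - 1)
                    logits = logits + table[flat]
                    w = np.exp(logits - logits.max(-1, keepdims=True))
                    w /= w.sum(-1, keepdims=True)
                    expected[coords[:, 0], coords[:, 1], coords[:, 2]] = w @ vi
        assert np.abs(out - expected).max() < 1e-5


class TestInit:
    def test_deterministic_per_seed(self):
        a = init_inductive_bias(2, 8, (4, 4, 4), seed=3)
        b = init_inductive_bias(2, 8, (4, 4, 4), seed=3)
        for ra, rb in zip(a.r_axial, b.r_axial):
            assert np.array_equal(ra.data, rb.data)
        assert np.array_equal(a.bias_table.data, b.bias_table.data)

    def test_zero_offset_entries_are_zero(self):
        p = init_inductive_bias(1, 8, (4, 4, 4))
        for r, m in zip(p.r_axial, (4, 4, 4)):
            assert np.allclose(r.data[:, m - 1, :], 0.0)

    def test_initialization_nondegenerate(self, rng):
        """Initialized positional terms vary across offsets and keep logits finite."""
        d, window = 8, (4, 4, 4)
        p = init_inductive_bias(1, d, window, dtype=np.float64)
        for r in p.r_axial:
            assert np.ptp(r.data) > 0
        tab = build_relative_index(window)
        q, k = rng.normal(size=(64, d)), rng.normal(size=(64, d))
        out = ib_logits(Tensor(q), Tensor(k), p, tab).data
        assert np.isfinite(out).all()
        zero = ib_logits(Tensor(q), Tensor(k),
                         zero_positional_params(1, d, window, dtype=np.float64),
                         tab).data
        assert np.abs(out - zero).max() > 0

    def test_sinusoid_shapes(self):
        pe = absolute_position_embedding(np.arange(-3, 4), 6)
        assert pe.shape == (7, 6)
        assert np.allclose(pe[3], [0, 1, 0, 1, 0, 1])  # position 0


class TestWindowAttentionModule:
    def test_output_shape_and_grad(self, rng):
        wa = WindowAttention(16, 2, (2, 2, 2), np.random.default_rng(0),
                             dtype=np.float64)
        x = Tensor(rng.normal(size=(4, 8, 16)), requires_grad=True)
        out = wa(x)
        assert out.shape == (4, 8, 16)
        out.sum().backward()
        assert np.isfinite(x.grad).all() and np.abs(x.grad).sum() > 0
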