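"""Inductive-biased multi-head self-attention (IB-MSA).

Windowed scaled-dot-product attention whose pre-softmax logits carry two
positional terms that depend only on the *relative* offset between tokens:

* a learned bias table ``B̂`` with one entry per admissible 3D offset
  (``(2M-1)^3`` entries for an ``M^3`` window), gathered into the pair matrix
  ``B`` through the relative index table, and
* axial embeddings ``r^W, r^H, r^D`` — one d-vector per per-axis offset —
  contracted with the query, so the positional contribution is
  query-dependent:

  ``l_ij = (q_i/sqrt(d)) · (k_j + r^W_{jx-ix} + r^H_{jy-iy} + r^D_{jz-iz})
  + B̂[rel(i, j)]``

The axial embeddings are initialized from differences of a fixed sinusoidal
absolute 1-D position code, which seeds the attention with locality and
translation equivariance before any training (the "inductive bias"); the
bias table starts at zero.  Both reduce the logit to the plain scaled dot
product when zeroed.

Canonical shapes: queries/keys/values are ``(N, heads, P, d)`` for N windows
of P tokens; axial embeddings are ``(heads, 2M_a-1, d)``; the bias table is
``(table_size, heads)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, Module, Linear, take_pairs, table_lookup
from .windowing import RelativeIndexTable, build_relative_index


@dataclass
class AttentionParams:
    """Positional parameters of one IB-MSA module."""

    heads: int
    d: int
    bias_table: Tensor                  # (table_size, heads)
    r_axial: tuple[Tensor, Tensor, Tensor]  # each (heads, 2M_a-1, d)

    @property
    def channels(self) -> int:
        return self.heads * self.d


def absolute_position_embedding(positions: np.ndarray, d: int) -> np.ndarray:
    """Sinusoidal 1-D position code, evaluated at (possibly signed) positions."""
    positions = np.asarray(positions, dtype=np.float64)
    half = (d + 1) // 2
    freqs = 1.0 / (10000.0 ** (2 * np.arange(half) / d))
    ang = positions[..., None] * freqs
    pe = np.zeros(positions.shape + (2 * half,))
    pe[..., 0::2] = np.sin(ang)
    pe[..., 1::2] = np.cos(ang)
    return pe[..., :d]


def init_inductive_bias(heads: int, d: int, window_size, seed: int = 0,
                        scale: float = 0.02, dtype=np.float32) -> AttentionParams:
    """Build positional parameters with the inductive-bias initialization.

    Axial embeddings start as differences of the sinusoidal absolute code
    (``r_a[o] = scale * (pe(o) - pe(0))``, so the zero offset maps exactly to
    zero) and the relative bias table starts at zero.  The construction is
    deterministic for a given seed and window size.
    """
    ws = window_size if not isinstance(window_size, int) else (window_size,) * 3
    table_size = int(np.prod([2 * m - 1 for m in ws]))
    rng = np.random.default_rng(seed)
    del rng  # reserved for stochastic variants; sinusoidal init is parameter-free
    r_axial = []
    for m in ws:
        offsets = np.arange(-(m - 1), m)
        pe = absolute_position_embedding(offsets, d)
        r = scale * (pe - absolute_position_embedding(np.zeros(1), d))
        r = np.broadcast_to(r[None], (heads, 2 * m - 1, d)).astype(dtype)
        r_axial.append(Tensor(r.copy(), requires_grad=True))
    bias = Tensor(np.zeros((table_size, heads), dtype=dtype), requires_grad=True)
    return AttentionParams(heads, d, bias, tuple(r_axial))


def zero_positional_params(heads: int, d: int, window_size, dtype=np.float32) -> AttentionParams:
    """All-zero positional terms: IB-MSA degenerates to vanilla attention."""
    ws = window_size if not isinstance(window_size, int) else (window_size,) * 3
    table_size = int(np.prod([2 * m - 1 for m in ws]))
    r = tuple(Tensor(np.zeros((heads, 2 * m - 1, d), dtype=dtype), requires_grad=True)
              for m in ws)
    return AttentionParams(heads, d, Tensor(np.zeros((table_size, heads), dtype=dtype),
                                            requires_grad=True), r)


def _canon(q) -> Tensor:
    q = q if isinstance(q, Tensor) else Tensor(q)
    if q.ndim == 2:                      # (P, d) -> (1, 1, P, d)
        q = q.reshape(1, 1, *q.shape)
    elif q.ndim == 3:                    # (N, P, d) -> (N, 1, P, d)
        q = q.reshape(q.shape[0], 1, *q.shape[1:])
    return q


def ib_logits(Q, K, params: AttentionParams, index_table: RelativeIndexTable) -> Tensor:
    """Pre-softmax attention logits with relative positional terms.

    Returns ``(N, heads, P, P)`` (leading axes squeezed back if the inputs
    were unbatched 2D matrices).
    """
    squeeze = (Q.ndim if isinstance(Q, Tensor) else np.asarray(Q).ndim) == 2
    q, k = _canon(Q), _canon(K)
    p = q.shape[-2]
    if index_table.index.shape[0] != p:
        raise ValueError(f"index table is for P={index_table.index.shape[0]}, got P={p}")
    qs = q * (1.0 / np.sqrt(params.d))
    logits = qs @ k.transpose(0, 1, 3, 2)
    for axis in range(3):
        r = params.r_axial[axis]                       # (heads, n_off, d)
        a = qs @ r.transpose(0, 2, 1)                  # (N, heads, P, n_off)
        logits = logits + take_pairs(a, index_table.axis_index[axis])
    b = table_lookup(params.bias_table, index_table.index)  # (P, P, heads)
    logits = logits + b.transpose(2, 0, 1)
    if squeeze and params.heads == 1:
        return logits.reshape(p, p)
    return logits


def ib_attention(Q, K, V, params: AttentionParams, index_table: RelativeIndexTable,
                 mask: np.ndarray | None = None) -> Tensor:
    """Biased softmax attention: ``SoftMax(QK^T/sqrt(d) + positional)V``.

    ``mask`` is an additive per-window (N, P, P) array; rows that block every
    position cannot be normalized and raise.
    """
    squeeze = (Q.ndim if isinstance(Q, Tensor) else np.asarray(Q).ndim) == 2
    q, k, v = _canon(Q), _canon(K), _canon(V)
    logits = ib_logits(q, k, params, index_table)
    if mask is not None:
        mask = np.asarray(mask)
        if mask.ndim == 2:
            mask = mask[None]
        if (mask < 0).all(axis=-1).any():
            raise ValueError("attention mask blocks an entire row; cannot normalize")
        logits = logits + Tensor(mask[:, None, :, :].astype(logits.dtype))
    attn = logits.softmax(axis=-1)
    out = attn @ v                                      # (N, heads, P, d)
    n, h, p, d = out.shape
    out = out.transpose(0, 2, 1, 3).reshape(n, p, h * d)
    if squeeze:
        out = out.reshape(p, h * d)
    return out


class WindowAttention(Module):
    """Multi-head IB-MSA over a batch of windows ``(N, P, C)``."""

    def __init__(self, channels: int, heads: int, window_size, rng: np.random.Generator,
                 position_mode: str = "inductive_bias", init_seed: int = 0,
                 dtype=np.float32):
        if channels % heads:
            raise ValueError(f"channels {channels} not divisible by heads {heads}")
        self.heads = heads
        self.d = channels // heads
        self.window_size = tuple(window_size) if not isinstance(window_size, int) \
            else (window_size,) * 3
        self.position_mode = position_mode
        self.qkv = Linear(channels, 3 * channels, rng, dtype)
        self.proj = Linear(channels, channels, rng, dtype)
        self.index_table = build_relative_index(self.window_size)
        if position_mode == "inductive_bias":
            self.pos = init_inductive_bias(heads, self.d, self.window_size,
                                           seed=init_seed, dtype=dtype)
        elif position_mode in ("relative_only", "none"):
            self.pos = zero_positional_params(heads, self.d, self.window_size, dtype)
            if position_mode == "none":
                for r in self.pos.r_axial:
                    r.requires_grad = False
                self.pos.bias_table.requires_grad = False
        else:
            raise ValueError(f"unknown position mode {position_mode!r}")
        # expose positional parameters for traversal
        self._bias_table = self.pos.bias_table
        self._r_w, self._r_h, self._r_d = self.pos.r_axial

    def forward(self, windows: Tensor, mask: np.ndarray | None = None) -> Tensor:
        n, p, c = windows.shape
        qkv = self.qkv(windows).reshape(n, p, 3, self.heads, self.d)
        qkv = qkv.transpose(2, 0, 3, 1, 4)              # (3, N, heads, P, d)
        q, k, v = qkv[0], qkv[1], qkv[2]
        out = ib_attention(q, k, v, self.pos, self.index_table, mask)
        return self.proj(out)
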