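"""Independent reference implementations used as test oracles.

These deliberately avoid the package's windowing/attention code paths: plain
numpy loops over physical windows, naive softmax, direct offset arithmetic.
"""

import numpy as np


def naive_softmax_attention(q, k, v):
    """Plain scaled-dot-product attention on one window."""
    d = q.shape[-1]
    logits = q @ k.T / np.sqrt(d)
    w = np.exp(logits - logits.max(-1, keepdims=True))
    w /= w.sum(-1, keepdims=True)
    return w @ v


def geometric_window_ib_attention(q, k, v, r_axial, bias_table, window, shift):
    """Biased attention evaluated separately on every physical window of the
    shifted partition (the 27-window brute force for an 8³ grid).

    ``r_axial``: three (2M_a-1, d) arrays; ``bias_table``: flat (table_size,)
    array; offsets are true spatial coordinate differences.
    """
    shape = q.shape[:3]
    d = q.shape[-1]
    out = np.empty_like(v)
    rw, rh, rd = r_axial
    n1, n2 = 2 * window[1] - 1, 2 * window[2] - 1

    def axis_bounds(n, m, s):
        cuts = [0, s] if s else [0]
        cuts += list(range(s + m, n, m)) + [n]
        return sorted(set(c for c in cuts if 0 <= c <= n))

    bx = axis_bounds(shape[0], window[0], shift[0])
    by = axis_bounds(shape[1], window[1], shift[1])
    bz = axis_bounds(shape[2], window[2], shift[2])
    for x0, x1 in zip(bx, bx[1:]):
        for y0, y1 in zip(by, by[1:]):
            for z0, z1 in zip(bz, bz[1:]):
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
                logits = logits + bias_table[flat]
                w = np.exp(logits - logits.max(-1, keepdims=True))
                w /= w.sum(-1, keepdims=True)
                out[coords[:, 0], coords[:, 1], coords[:, 2]] = w @ vi
    return out
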