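"""3D window partitioning for shifted-window self-attention.

A token grid of spatial shape ``(h, w, d)`` with ``C`` channels is split into
non-overlapping local windows of size ``(S_H, S_W, S_D)``.  The shifted
configuration displaces the window grid by half a window; rather than paying
for the larger number of geometric windows this creates, the grid is rolled
toroidally (cyclic shift) so the regular partition can be reused, and an
additive attention mask blocks token pairs that were not spatial neighbours
before the roll — the "efficient batch computation" of the Swin family.

All functions accept autodiff tensors or plain arrays; gradients flow through
partitioning, shifting and reversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor

#: additive mask sentinel for blocked attention pairs (finite so that softmax
#: stays NaN-free even in degenerate corners)
MASK_BLOCK = -1e9


@dataclass
class TokenGrid:
    """Hierarchical token tensor: spatial (h, w, d) grid of C-channel tokens."""

    tokens: Tensor
    stage: int = 0

    def __post_init__(self):
        if not isinstance(self.tokens, Tensor):
            self.tokens = Tensor(self.tokens)
        if self.tokens.ndim != 4:
            raise ValueError(f"token grid must be 4D (h, w, d, C), got {self.tokens.shape}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.tokens.shape[:3]

    @property
    def channels(self) -> int:
        return self.tokens.shape[3]


@dataclass
class WindowSet:
    """Batched windows (N, P, C) plus the bookkeeping to invert partitioning."""

    windows: Tensor
    window_size: tuple[int, int, int]
    shift: tuple[int, int, int]
    source_shape: tuple[int, int, int]      # pre-pad spatial shape
    padded_shape: tuple[int, int, int]
    stage: int = 0

    @property
    def num_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def tokens_per_window(self) -> int:
        return self.windows.shape[1]


@dataclass
class RelativeIndexTable:
    """Maps ordered token pairs of a window to relative-offset table entries.

    ``index[i, j]`` addresses the flattened ``(2M_H-1)x(2M_W-1)x(2M_D-1)``
    bias table; ``axis_index[a][i, j]`` addresses the per-axis embedding of
    offset ``coord_a(j) - coord_a(i)`` (shifted to start at 0).
    """

    window_size: tuple[int, int, int]
    index: np.ndarray = field(repr=False)
    axis_index: tuple[np.ndarray, np.ndarray, np.ndarray] = field(repr=False)

    @property
    def table_size(self) -> int:
        return int(np.prod([2 * m - 1 for m in self.window_size]))

    @property
    def offsets_per_axis(self) -> tuple[int, int, int]:
        return tuple(2 * m - 1 for m in self.window_size)


def _as3(v) -> tuple[int, int, int]:
    if isinstance(v, int):
        return (v, v, v)
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected 3 components, got {v!r}")
    return t


def pad_to_multiple(grid: TokenGrid, window_size) -> TokenGrid:
    """Zero-pad the high side of each axis up to a multiple of the window."""
    ws = _as3(window_size)
    h, w, d = grid.spatial_shape
    pads = [(-s) % m for s, m in zip((h, w, d), ws)]
    if not any(pads):
        return grid
    padded = grid.tokens.pad(((0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
    return TokenGrid(padded, grid.stage)


def partition_windows(grid: TokenGrid, window_size, shift=(0, 0, 0)) -> WindowSet:
    """Split a token grid into non-overlapping windows of ``window_size``.

    Every token lands in exactly one window; grids whose sides are not
    divisible by the window are zero-padded first (pair with an attention
    mask from :func:`build_attention_mask` so padding cannot leak).
    """
    ws = _as3(window_size)
    if any(m <= 0 for m in ws):
        raise ValueError(f"window size must be positive, got {ws}")
    source_shape = grid.spatial_shape
    grid = pad_to_multiple(grid, ws)
    h, w, d = grid.spatial_shape
    c = grid.channels
    t = grid.tokens.reshape(h // ws[0], ws[0], w // ws[1], ws[1], d // ws[2], ws[2], c)
    t = t.transpose(0, 2, 4, 1, 3, 5, 6)
    n = (h // ws[0]) * (w // ws[1]) * (d // ws[2])
    windows = t.reshape(n, ws[0] * ws[1] * ws[2], c)
    return WindowSet(windows, ws, _as3(shift), source_shape, (h, w, d), grid.stage)


def reverse_windows(ws: WindowSet) -> TokenGrid:
    """Exact inverse of :func:`partition_windows`, including unpadding."""
    m = ws.window_size
    h, w, d = ws.padded_shape
    c = ws.windows.shape[2]
    if ws.num_windows != (h // m[0]) * (w // m[1]) * (d // m[2]):
        raise ValueError("window count inconsistent with padded source shape")
    t = ws.windows.reshape(h // m[0], w // m[1], d // m[2], m[0], m[1], m[2], c)
    t = t.transpose(0, 3, 1, 4, 2, 5, 6).reshape(h, w, d, c)
    sh, sw, sd = ws.source_shape
    if (sh, sw, sd) != (h, w, d):
        t = t[:sh, :sw, :sd, :]
    return TokenGrid(t, ws.stage)


def cyclic_shift(grid: TokenGrid, shift, inverse: bool = False) -> TokenGrid:
    """Toroidally roll the token grid by ``-shift`` (or ``+shift`` to undo).

    Rolling the content backwards lets the regular window partition realise
    the shifted-window configuration.
    """
    s = _as3(shift)
    roll = tuple(x if inverse else -x for x in s)
    if not any(roll):
        return grid
    return TokenGrid(grid.tokens.roll(roll, axis=(0, 1, 2)), grid.stage)


def geometric_window_count(source_shape, window_size, shift) -> int:
    """Number of physical windows of the (possibly shifted) partition.

    With a nonzero shift each axis gains one partial window: an 8-token axis
    with window 4 and shift 2 splits into 3 intervals, hence the 2x2x2=8
    regular windows become 3x3x3=27 geometric ones.
    """
    shape, ws, s = _as3(source_shape), _as3(window_size), _as3(shift)
    count = 1
    for n, m, sh in zip(shape, ws, s):
        n_pad = n + ((-n) % m)
        count *= n_pad // m + (1 if sh % m else 0)
    return count


def _region_labels(size: int, window: int, shift: int) -> np.ndarray:
    """Region labelling of one axis, in rolled coordinates.

    After the grid is rolled by ``-shift``, positions ``[0, size-window)``
    fill complete shifted windows; the final rolled window mixes the two
    wrap-seam pieces ``[size-window, size-shift)`` and ``[size-shift, size)``,
    which must not attend to each other.
    """
    labels = np.zeros(size, dtype=np.int64)
    if shift % window == 0:
        return labels
    idx = np.arange(size)
    labels[(idx >= size - window) & (idx < size - shift)] = 1
    labels[idx >= size - shift] = 2
    return labels


def build_attention_mask(source_shape, window_size, shift) -> np.ndarray:
    """Per-window additive mask (N, P, P) for cyclic-shifted attention.

    Token pairs originating from different pre-shift regions (or involving
    exactly one padded token) are blocked with :data:`MASK_BLOCK`; the mask is
    all zeros when the shift is zero and the grid needs no padding.
    """
    shape, ws, s = _as3(source_shape), _as3(window_size), _as3(shift)
    padded = tuple(n + ((-n) % m) for n, m in zip(shape, ws))
    axis_labels = [_region_labels(n, m, sh) for n, m, sh in zip(padded, ws, s)]
    lab = (axis_labels[0][:, None, None] * 9
           + axis_labels[1][None, :, None] * 3
           + axis_labels[2][None, None, :])
    # padded voxels form their own region so they only attend to each other
    pad_mark = np.zeros(padded, dtype=bool)
    if padded != tuple(shape):
        pad_mark[:] = True
        pad_mark[:shape[0], :shape[1], :shape[2]] = False
        pad_mark = np.roll(pad_mark, tuple(-x for x in s), axis=(0, 1, 2))
        lab = np.where(pad_mark, 27, lab)
    wlab = partition_windows(TokenGrid(lab[..., None].astype(np.float64)), ws).windows.data[..., 0]
    mask = np.where(wlab[:, :, None] == wlab[:, None, :], 0.0, MASK_BLOCK)
    return mask


def build_relative_index(window_size) -> RelativeIndexTable:
    """Enumerate relative offsets between all ordered token pairs of a window.

    Per-axis offsets span ``[-(M-1), M-1]``; the joint table therefore has
    ``(2M_H-1)(2M_W-1)(2M_D-1)`` entries and the diagonal pair ``i == j``
    maps to the (0, 0, 0)-offset entry.
    """
    ws = _as3(window_size)
    if any(m < 1 for m in ws):
        raise ValueError("window sides must be >= 1")
    coords = np.stack(np.meshgrid(*(np.arange(m) for m in ws), indexing="ij"),
                      axis=-1).reshape(-1, 3)                       # (P, 3)
    diff = coords[None, :, :] - coords[:, None, :]                  # j - i
    axis_index = tuple(diff[..., a] + (ws[a] - 1) for a in range(3))
    n1, n2 = 2 * ws[1] - 1, 2 * ws[2] - 1
    index = (axis_index[0] * n1 + axis_index[1]) * n2 + axis_index[2]
    return RelativeIndexTable(ws, index.astype(np.int64),
                              tuple(a.astype(np.int64) for a in axis_index))
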