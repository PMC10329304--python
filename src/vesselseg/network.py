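"""U-shaped 3D shifted-window transformer for vessel segmentation.

Architecture: a voxel-wise convolutional patch embedding (total stride 4,
large-kernel first convolution) produces a token grid at 1/4 resolution with
``C`` channels; a hierarchy of transformer stages — each a run of
regular/shifted IB-MSA block pairs — is interleaved with strided-convolution
down-sampling (channels double when resolution halves).  The decoder mirrors
the encoder with transposed-convolution up-sampling and skip connections at
every resolution (including the embedding output), then expands back to full
voxel resolution where a parallel convolutional local-feature path is fused
in before the two-class softmax head.

Channel 0 of the output is the vessel (foreground) probability, channel 1
the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (Tensor, Module, Linear, LayerNorm, MLP, Conv3d, ConvTranspose3d,
                 concat, conv_transpose3d)
from .windowing import (TokenGrid, partition_windows, reverse_windows, cyclic_shift,
                        build_attention_mask, pad_to_multiple)
from .attention import WindowAttention


@dataclass
class StageSpec:
    """One resolution level of the transformer hierarchy."""

    depth: int                 # number of blocks; must be even (regular+shifted pairs)
    channels: int
    heads: int
    window_size: tuple[int, int, int]

    def __post_init__(self):
        if self.depth % 2:
            raise ValueError("stage depth must be even (regular/shifted alternation)")


@dataclass
class NetworkOutput:
    """Per-voxel class probabilities at input resolution."""

    probabilities: Tensor      # (X, Y, Z, 2); softmax-normalized over channels

    @property
    def foreground(self) -> np.ndarray:
        return self.probabilities.data[..., 0]


def complexity_estimate(h: int, w: int, d: int, channels: int, window) -> int:
    """Multiply count of windowed IB-MSA on an ``h x w x d`` token grid.

    ``4 h w d C^2`` for the projections plus ``2 S_H S_W S_D h w d C`` for the
    attention itself — linear in the grid size, unlike global attention whose
    second term is quadratic in ``h w d``.
    """
    if min(h, w, d, channels) <= 0:
        raise ValueError("sizes must be positive")
    sh, sw, sd = (window,) * 3 if isinstance(window, int) else tuple(window)
    return 4 * h * w * d * channels ** 2 + 2 * sh * sw * sd * h * w * d * channels


def _as_input_tensor(patch) -> Tensor:
    x = patch.data if hasattr(patch, "data") and not isinstance(patch, Tensor) else patch
    if isinstance(x, Tensor):
        t = x
    else:
        t = Tensor(np.asarray(x))
    if t.ndim == 3:
        t = t.reshape(*t.shape, 1)
    if t.ndim != 4:
        raise ValueError(f"expected a 3D patch, got shape {t.shape}")
    return t


class PatchEmbed(Module):
    """Voxel-wise embedding: successive strided convs (total stride 4/axis),
    each followed by GELU and layer normalization."""

    def __init__(self, channels: int, rng, kernels=(7, 3), strides=(2, 2), dtype=np.float32):
        if int(np.prod(strides)) != 4:
            raise ValueError("embedding strides must multiply to 4 per axis")
        mid = max(channels // 2, 1)
        self.conv1 = Conv3d(1, mid, kernels[0], strides[0], kernels[0] // 2, rng, dtype)
        self.norm1 = LayerNorm(mid, dtype)
        self.conv2 = Conv3d(mid, channels, kernels[1], strides[1], kernels[1] // 2, rng, dtype)
        self.norm2 = LayerNorm(channels, dtype)

    def forward(self, x: Tensor) -> TokenGrid:
        if any(s % 4 for s in x.shape[:3]):
            raise ValueError(f"input spatial shape {x.shape[:3]} not divisible by 4")
        t = self.norm1(self.conv1(x).gelu())
        t = self.norm2(self.conv2(t).gelu())
        return TokenGrid(t)


class TransformerBlock(Module):
    """One Eq.-style block: LN → (shifted) window IB-MSA → residual,
    then LN → MLP → residual."""

    _mask_cache: dict = {}

    def __init__(self, channels: int, heads: int, window_size, shifted: bool, rng,
                 position_mode="inductive_bias", mlp_ratio=4, init_seed=0, dtype=np.float32):
        self.window_size = tuple(window_size)
        self.shift = tuple(m // 2 for m in self.window_size) if shifted else (0, 0, 0)
        self.norm1 = LayerNorm(channels, dtype)
        self.attn = WindowAttention(channels, heads, self.window_size, rng,
                                    position_mode=position_mode, init_seed=init_seed,
                                    dtype=dtype)
        self.norm2 = LayerNorm(channels, dtype)
        self.mlp = MLP(channels, mlp_ratio * channels, rng, dtype)

    def _mask(self, shape):
        key = (shape, self.window_size, self.shift)
        if key not in TransformerBlock._mask_cache:
            m = build_attention_mask(shape, self.window_size, self.shift)
            TransformerBlock._mask_cache[key] = None if (m == 0).all() else m
        return TransformerBlock._mask_cache[key]

    def forward(self, grid: TokenGrid) -> TokenGrid:
        h0, w0, d0 = grid.spatial_shape
        x = grid.tokens
        # pad to window multiples *before* the cyclic shift so the attention
        # mask (which labels padding on the padded grid) stays consistent
        h = pad_to_multiple(TokenGrid(self.norm1(x)), self.window_size)
        shifted = cyclic_shift(h, self.shift)
        ws = partition_windows(shifted, self.window_size, self.shift)
        attended = self.attn(ws.windows, self._mask((h0, w0, d0)))
        ws.windows = attended
        h = cyclic_shift(reverse_windows(ws), self.shift, inverse=True).tokens
        if h.shape[:3] != (h0, w0, d0):
            h = h[:h0, :w0, :d0, :]
        x = x + h
        x = x + self.mlp(self.norm2(x))
        return TokenGrid(x, grid.stage)


class TransformerStage(Module):
    """A run of regular/shifted block pairs at one resolution."""

    def __init__(self, spec: StageSpec, rng, position_mode="inductive_bias",
                 first_stage=False, dtype=np.float32):
        self.blocks = [
            TransformerBlock(spec.channels, spec.heads, spec.window_size,
                             shifted=bool(i % 2), rng=rng,
                             position_mode=position_mode if (first_stage or
                                                             position_mode != "inductive_bias")
                             else "relative_only",
                             dtype=dtype)
            for i in range(spec.depth)
        ]

    def forward(self, grid: TokenGrid) -> TokenGrid:
        for blk in self.blocks:
            grid = blk(grid)
        return grid


class Downsample(Module):
    """Halve the spatial sides and double the channels.

    ``conv`` (default): stride-2 convolution + GELU + LayerNorm.
    ``patch_merging``: concatenate 2x2x2 neighbours and project linearly.
    """

    def __init__(self, channels: int, rng, mode: str = "conv", dtype=np.float32):
        self.mode = mode
        if mode == "conv":
            self.conv = Conv3d(channels, 2 * channels, 2, 2, 0, rng, dtype)
            self.norm = LayerNorm(2 * channels, dtype)
        elif mode == "patch_merging":
            self.reduce = Linear(8 * channels, 2 * channels, rng, dtype)
            self.norm = LayerNorm(2 * channels, dtype)
        else:
            raise ValueError(f"unknown downsample mode {mode!r}")

    def forward(self, grid: TokenGrid) -> TokenGrid:
        h, w, d = grid.spatial_shape
        if any(s % 2 for s in (h, w, d)):
            grid = TokenGrid(grid.tokens.pad(((0, h % 2), (0, w % 2), (0, d % 2), (0, 0))),
                             grid.stage)
            h, w, d = grid.spatial_shape
        if self.mode == "conv":
            t = self.norm(self.conv(grid.tokens).gelu())
        else:
            c = grid.channels
            t = grid.tokens.reshape(h // 2, 2, w // 2, 2, d // 2, 2, c)
            t = t.transpose(0, 2, 4, 1, 3, 5, 6).reshape(h // 2, w // 2, d // 2, 8 * c)
            t = self.norm(self.reduce(t))
        return TokenGrid(t, grid.stage + 1)


def _trilinear_kernel(dtype):
    k = np.array([0.25, 0.75, 0.75, 0.25], dtype=dtype)
    return k[:, None, None] * k[None, :, None] * k[None, None, :]


class Upsample(Module):
    """Double the spatial sides and halve the channels.

    ``transposed_conv`` (default): stride-2 transposed convolution.
    ``trilinear``: fixed linear-interpolation kernel then a channel projection.
    ``patch_expanding``: linear projection to 2x2x2 sub-tokens.
    """

    def __init__(self, channels: int, rng, mode: str = "transposed_conv", dtype=np.float32):
        self.mode = mode
        out = channels // 2
        if mode == "transposed_conv":
            self.deconv = ConvTranspose3d(channels, out, 2, 2, rng, dtype)
            self.norm = LayerNorm(out, dtype)
        elif mode == "trilinear":
            self.proj = Linear(channels, out, rng, dtype)
            self.norm = LayerNorm(out, dtype)
            self._kern = _trilinear_kernel(dtype)
        elif mode == "patch_expanding":
            self.expand = Linear(channels, 8 * out, rng, dtype)
            self.norm = LayerNorm(out, dtype)
        else:
            raise ValueError(f"unknown upsample mode {mode!r}")

    def forward(self, grid: TokenGrid) -> TokenGrid:
        h, w, d = grid.spatial_shape
        c = grid.channels
        if self.mode == "transposed_conv":
            t = self.norm(self.deconv(grid.tokens).gelu())
        elif self.mode == "trilinear":
            t = self.proj(grid.tokens)
            kern = Tensor(np.broadcast_to(
                self._kern[..., None, None] * np.eye(t.shape[-1], dtype=self._kern.dtype),
                self._kern.shape + (t.shape[-1], t.shape[-1])).copy())
            up = conv_transpose3d(t, kern, None, 2)
            ones = conv_transpose3d(Tensor(np.ones(t.shape[:3] + (1,), dtype=t.dtype.type)),
                                    Tensor(self._kern[..., None, None]), None, 2)
            t = (up * ones.detach() ** -1.0)[1:-1, 1:-1, 1:-1, :]
            t = self.norm(t)
        else:
            t = self.expand(grid.tokens).reshape(h, w, d, 2, 2, 2, c // 2)
            t = t.transpose(0, 3, 1, 4, 2, 5, 6).reshape(2 * h, 2 * w, 2 * d, c // 2)
            t = self.norm(t)
        return TokenGrid(t, max(grid.stage - 1, 0))


class LocalFeaturePath(Module):
    """Full-resolution convolutional features (large kernels) fused with the
    decoder output before the head; supplements precise spatial detail the
    token path loses to the stride-4 embedding."""

    def __init__(self, out_channels: int, rng, kernels=(7, 3), dtype=np.float32):
        mid = max(out_channels // 2, 4)
        self.conv1 = Conv3d(1, mid, kernels[0], 1, kernels[0] // 2, rng, dtype)
        self.norm1 = LayerNorm(mid, dtype)
        self.conv2 = Conv3d(mid, out_channels, kernels[1], 1, kernels[1] // 2, rng, dtype)
        self.norm2 = LayerNorm(out_channels, dtype)

    def forward(self, x: Tensor) -> TokenGrid:
        t = self.norm1(self.conv1(x).gelu())
        t = self.norm2(self.conv2(t).gelu())
        return TokenGrid(t)


class IBSwinUNet3D(Module):
    """The full segmentation network.

    Parameters mirror the run configuration: ``base_channels`` is the token
    width C after embedding, ``depths`` the per-stage block counts (each
    even), ``window_size`` the local attention volume.  ``num_stages`` is
    ``len(depths)``; channels double at each deeper stage.
    """

    def __init__(self, base_channels: int = 128, depths=(2, 2, 2), window_size=(4, 4, 4),
                 heads_per_stage=None, position_mode: str = "inductive_bias",
                 downsample_mode: str = "conv", upsample_mode: str = "transposed_conv",
                 local_path: bool = True, embed_kernels=(7, 3), mlp_ratio: int = 4,
                 seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.dtype = np.dtype(dtype)
        ws = (window_size,) * 3 if isinstance(window_size, int) else tuple(window_size)
        n = len(depths)
        chans = [base_channels * 2 ** i for i in range(n)]
        if heads_per_stage is None:
            heads_per_stage = [max(c // 32, 1) for c in chans]
        self.stage_specs = [StageSpec(depths[i], chans[i], heads_per_stage[i], ws)
                            for i in range(n)]
        self.local_path_enabled = local_path

        self.embed = PatchEmbed(base_channels, rng, kernels=embed_kernels, dtype=dtype)
        self.enc_stages = [TransformerStage(s, rng, position_mode, first_stage=(i == 0),
                                            dtype=dtype)
                           for i, s in enumerate(self.stage_specs)]
        self.downs = [Downsample(chans[i], rng, downsample_mode, dtype)
                      for i in range(n - 1)]
        self.ups = [Upsample(chans[i], rng, upsample_mode, dtype)
                    for i in range(n - 1, 0, -1)]
        self.skip_fuse = [Linear(2 * chans[i], chans[i], rng, dtype)
                          for i in range(n - 2, -1, -1)]
        self.dec_stages = [TransformerStage(self.stage_specs[i], rng, position_mode,
                                            dtype=dtype)
                           for i in range(n - 2, -1, -1)]
        self.embed_fuse = Linear(2 * base_channels, base_channels, rng, dtype)
        c4, c16 = max(base_channels // 2, 2), max(base_channels // 4, 2)
        self.expand1 = ConvTranspose3d(base_channels, c4, 2, 2, rng, dtype)
        self.expand_norm1 = LayerNorm(c4, dtype)
        self.expand2 = ConvTranspose3d(c4, c16, 2, 2, rng, dtype)
        self.expand_norm2 = LayerNorm(c16, dtype)
        if local_path:
            self.local = LocalFeaturePath(c16, rng, kernels=embed_kernels, dtype=dtype)
            self.head = Linear(2 * c16, 2, rng, dtype)
        else:
            self.head = Linear(c16, 2, rng, dtype)

    # -- pieces exposed for composition/tests --------------------------------

    def patch_embed(self, patch) -> TokenGrid:
        x = _as_input_tensor(patch)
        if x.dtype != self.dtype:
            x = Tensor(x.data.astype(self.dtype), requires_grad=x.requires_grad)
        return self.embed(x)

    def forward(self, patch) -> NetworkOutput:
        x = _as_input_tensor(patch)
        if x.dtype != self.dtype:
            x = Tensor(x.data.astype(self.dtype), requires_grad=x.requires_grad)
        grid = self.embed(x)
        embed_out = grid
        skips = []
        for i, stage in enumerate(self.enc_stages):
            grid = stage(grid)
            if i < len(self.enc_stages) - 1:
                skips.append(grid)
                grid = self.downs[i](grid)
        for up, fuse, dec, skip in zip(self.ups, self.skip_fuse, self.dec_stages,
                                       reversed(skips)):
            grid = up(grid)
            grid = _match_and_fuse(grid, skip, fuse)
            grid = dec(grid)
        t = concat([grid.tokens, embed_out.tokens], axis=-1)
        t = self.embed_fuse(t)
        t = self.expand_norm1(self.expand1(t).gelu())
        t = self.expand_norm2(self.expand2(t).gelu())
        if self.local_path_enabled:
            loc = self.local(x)
            t = concat([t, loc.tokens], axis=-1)
        logits = self.head(t)
        return NetworkOutput(logits.softmax(axis=-1))


def _match_and_fuse(grid: TokenGrid, skip: TokenGrid, fuse: Linear) -> TokenGrid:
    """Crop an upsampled grid to its skip partner (padding parity) and fuse."""
    gh, gw, gd = grid.spatial_shape
    sh, sw, sd = skip.spatial_shape
    t = grid.tokens
    if (gh, gw, gd) != (sh, sw, sd):
        t = t[:sh, :sw, :sd, :]
    t = fuse(concat([t, skip.tokens], axis=-1))
    return TokenGrid(t, skip.stage)


def save_checkpoint(model: IBSwinUNet3D, path, config_hash: str = "", extra: dict | None = None):
    """Serialize model weights (plus a config hash) to a single .npz file."""
    state = model.state_dict()
    meta = {"__config_hash__": np.array(config_hash)}
    if extra:
        meta.update({f"__extra_{k}__": np.asarray(v) for k, v in extra.items()})
    np.savez(path, **state, **meta)


def load_checkpoint(model: IBSwinUNet3D, path) -> str:
    """Load weights saved by :func:`save_checkpoint`; returns the config hash."""
    with np.load(path, allow_pickle=False) as z:
        state = {k: z[k] for k in z.files if not k.startswith("__")}
        chash = str(z["__config_hash__"]) if "__config_hash__" in z.files else ""
    model.load_state_dict(state)
    return chash
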