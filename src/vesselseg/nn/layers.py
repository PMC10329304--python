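"""Neural-network building blocks on top of the autodiff core.

Layout conventions: volumetric activations are channels-last ``(X, Y, Z, C)``;
convolution weights are ``(kx, ky, kz, C_in, C_out)``; dense weights are
``(C_in, C_out)``.  Convolutions process the output grid in chunks along the
first spatial axis so that the im2col buffer stays bounded regardless of the
volume size.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

# soft cap on the im2col scratch buffer, in array elements
_IM2COL_CHUNK_ELEMS = 24_000_000


class Module:
    """Minimal parameter container with recursive traversal."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=p.data.dtype)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(rng: np.random.Generator, shape, fan_in: int, dtype) -> Tensor:
    scale = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-scale, scale, size=shape).astype(dtype), requires_grad=True)


class Linear(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.weight = _param(rng, (c_in, c_out), c_in, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    """Normalization over the trailing channel axis."""

    def __init__(self, c: int, dtype=np.float32, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(c, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=dtype), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        m = x.mean(axis=-1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (v + self.eps) ** -0.5 * self.gamma + self.beta


class MLP(Module):
    """Two-layer GELU feed-forward block used inside transformer blocks."""

    def __init__(self, c: int, hidden: int, rng, dtype=np.float32):
        self.fc1 = Linear(c, hidden, rng, dtype)
        self.fc2 = Linear(hidden, c, rng, dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int, padding: int) -> Tensor:
    """Strided 3D convolution, channels-last, via chunked im2col."""
    kx, ky, kz, cin, cout = w.shape
    s, p = stride, padding
    xp = np.pad(x.data, ((p, p), (p, p), (p, p), (0, 0)))
    ox = (xp.shape[0] - kx) // s + 1
    oy = (xp.shape[1] - ky) // s + 1
    oz = (xp.shape[2] - kz) // s + 1
    wmat = w.data.reshape(kx * ky * kz * cin, cout)

    chunk = max(1, _IM2COL_CHUNK_ELEMS // max(oy * oz * kx * ky * kz * cin, 1))
    out = np.empty((ox, oy, oz, cout), dtype=x.data.dtype)
    ranges = [(o0, min(o0 + chunk, ox)) for o0 in range(0, ox, chunk)]

    def patches_for(o0, o1):
        sl = xp[o0 * s: (o1 - 1) * s + kx]
        win = sliding_window_view(sl, (kx, ky, kz), axis=(0, 1, 2))
        win = win[::s, ::s, ::s].transpose(0, 1, 2, 4, 5, 6, 3)
        return np.ascontiguousarray(win)  # (o1-o0, oy, oz, kx, ky, kz, cin)

    for o0, o1 in ranges:
        pt = patches_for(o0, o1)
        out[o0:o1] = (pt.reshape(-1, wmat.shape[0]) @ wmat).reshape(o1 - o0, oy, oz, cout)
    if b is not None:
        out = out + b.data

    def backward(g):
        if w.requires_grad or b is not None and b.requires_grad:
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 1, 2)))
        gw = np.zeros_like(w.data) if w.requires_grad else None
        gx = np.zeros_like(xp) if x.requires_grad else None
        for o0, o1 in ranges:
            gm = g[o0:o1].reshape(-1, cout)
            if gw is not None:
                pt = patches_for(o0, o1).reshape(-1, wmat.shape[0])
                gw += (pt.T @ gm).reshape(w.shape)
            if gx is not None:
                gpt = (gm @ wmat.T).reshape(o1 - o0, oy, oz, kx, ky, kz, cin)
                for i in range(kx):
                    for j in range(ky):
                        for l in range(kz):
                            gx[o0 * s + i: (o1 - 1) * s + i + 1: s,
                               j: (oy - 1) * s + j + 1: s,
                               l: (oz - 1) * s + l + 1: s] += gpt[:, :, :, i, j, l]
        if gw is not None:
            w._accum(gw)
        if gx is not None:
            nx, ny, nz = x.shape[:3]
            x._accum(gx[p: p + nx, p: p + ny, p: p + nz])

    return Tensor._make(out, (x, w) + ((b,) if b is not None else ()), backward)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Transposed 3D convolution (fractionally-strided), channels-last."""
    kx, ky, kz, cin, cout = w.shape
    s = stride
    nx, ny, nz = x.shape[:3]
    out = np.zeros(((nx - 1) * s + kx, (ny - 1) * s + ky, (nz - 1) * s + kz, cout),
                   dtype=x.data.dtype)
    for i in range(kx):
        for j in range(ky):
            for l in range(kz):
                out[i: i + (nx - 1) * s + 1: s,
                    j: j + (ny - 1) * s + 1: s,
                    l: l + (nz - 1) * s + 1: s] += x.data @ w.data[i, j, l]
    if b is not None:
        out = out + b.data

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        gw = np.zeros_like(w.data) if w.requires_grad else None
        for i in range(kx):
            for j in range(ky):
                for l in range(kz):
                    gsl = g[i: i + (nx - 1) * s + 1: s,
                            j: j + (ny - 1) * s + 1: s,
                            l: l + (nz - 1) * s + 1: s]
                    if gx is not None:
                        gx += gsl @ w.data[i, j, l].T
                    if gw is not None:
                        gw[i, j, l] = np.tensordot(x.data, gsl, axes=([0, 1, 2], [0, 1, 2]))
        if gx is not None:
            x._accum(gx)
        if gw is not None:
            w._accum(gw)

    return Tensor._make(out, (x, w) + ((b,) if b is not None else ()), backward)


class Conv3d(Module):
    def __init__(self, c_in, c_out, kernel, stride, padding, rng, dtype=np.float32):
        k = (kernel,) * 3 if isinstance(kernel, int) else tuple(kernel)
        fan_in = int(np.prod(k)) * c_in
        self.weight = _param(rng, k + (c_in, c_out), fan_in, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, c_in, c_out, kernel, stride, rng, dtype=np.float32):
        k = (kernel,) * 3 if isinstance(kernel, int) else tuple(kernel)
        fan_in = int(np.prod(k)) * c_in
        self.weight = _param(rng, k + (c_in, c_out), fan_in, dtype)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, self.stride)
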