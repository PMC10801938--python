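"""Neural-network building blocks over the autograd engine.

All sequence tensors are laid out batch x time x channels.  Convolutions are
causal: windows are gathered from a left-zero-padded sequence so output t
never reads an input later than t.  Weight initialization is He-normal from
an explicit ``numpy.random.Generator`` so builds are reproducible.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Sequence

import numpy as np

from .autograd import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "CausalConv1d",
    "DepthwiseSeparableConv1d",
    "BatchNorm1d",
    "Dropout",
    "SEBlock",
    "MultiHeadSelfAttention",
    "causal_dilated_conv",
]

DTYPE = np.float32


class Module:
    """Minimal module base: parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> List[Tensor]:
        params: List[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> List[np.ndarray]:
        """All learnable parameter arrays plus buffers, in a stable order."""
        arrays = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm1d):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        own = self.state_arrays()
        if len(own) != len(arrays):
            raise ValueError("state size mismatch")
        for dst, src in zip(own, arrays):
            dst[...] = src

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / max(fan_in, 1)), size=shape).astype(DTYPE)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Tensor(_he_normal(rng, (n_in, n_out), n_in), requires_grad=True)
        self.bias = (
            Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


def _conv_window_index(n_in: int, k: int, dilation: int, stride: int) -> np.ndarray:
    """Window gather index into the left-padded sequence.

    Output position t (pre-stride) reads padded indices t + dilation*j for
    j = 0..k-1, i.e. taps ordered oldest-first: tap j corresponds to input
    sample t - dilation*(k-1-j) in original coordinates.
    """
    n_out = -(-n_in // stride)  # ceil division
    starts = np.arange(n_out) * stride
    return starts[:, None] + dilation * np.arange(k)[None, :]


class CausalConv1d(Module):
    """Dilated causal 1-d convolution, (B, L, Cin) -> (B, ceil(L/s), Cout).

    Implements Y(t) = sum_i w(i) X(t - d*i) with zero left-padding of
    d*(k-1) samples, then keeps every ``stride``-th output.
    """

    def __init__(
        self,
        n_in: int,
        n_out: int,
        kernel_size: int,
        rng: np.random.Generator,
        dilation: int = 1,
        stride: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        if dilation < 1 or stride < 1:
            raise ValueError("dilation and stride must be >= 1")
        self.n_in, self.n_out = n_in, n_out
        self.kernel_size, self.dilation, self.stride = kernel_size, dilation, stride
        fan_in = n_in * kernel_size
        # stored oldest-tap-first, flattened (k*Cin, Cout) for the matmul
        self.weight = Tensor(
            _he_normal(rng, (kernel_size * n_in, n_out), fan_in), requires_grad=True
        )
        self.bias = (
            Tensor(np.zeros(n_out, dtype=DTYPE), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        b, n, c = x.shape
        if c != self.n_in:
            raise ValueError(f"expected {self.n_in} input channels, got {c}")
        k, d = self.kernel_size, self.dilation
        pad = d * (k - 1)
        xp = x.pad_time(pad, axis=1) if pad else x
        n_out = -(-n // self.stride)
        win = xp.take_windows_strided(k, d, self.stride, n_out)  # (B, Lout, k, Cin)
        flat = win.reshape(b, n_out, k * c)
        y = flat @ self.weight
        return y + self.bias if self.bias is not None else y


def causal_dilated_conv(
    x: np.ndarray, w: np.ndarray, dilation: int = 1, stride: int = 1
) -> np.ndarray:
    """Functional single-channel dilated causal convolution.

    ``w[i]`` multiplies the sample ``dilation * i`` steps in the past:
    Y(t) = sum_{i=0}^{k-1} w(i) * X(t - dilation*i), with zero left padding
    and output length ceil(len(x) / stride).
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    k = w.size
    pad = dilation * (k - 1)
    xp = np.concatenate([np.zeros(pad), x])
    idx = _conv_window_index(x.size, k, dilation, stride)
    # gather is oldest-first; reverse taps so w[0] hits the current sample
    return xp[idx] @ w[::-1]


class DepthwiseSeparableConv1d(Module):
    """Depthwise + pointwise causal convolution preserving sequence length."""

    def __init__(
        self,
        n_in: int,
        n_out: int,
        kernel_size: int,
        rng: np.random.Generator,
        dilation: int = 1,
    ):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.kernel_size, self.dilation = kernel_size, dilation
        # depthwise: one k-tap filter per input channel (oldest-first)
        self.dw_weight = Tensor(
            _he_normal(rng, (kernel_size, n_in), kernel_size), requires_grad=True
        )
        self.pw = Linear(n_in, n_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, n, c = x.shape
        k, d = self.kernel_size, self.dilation
        pad = d * (k - 1)
        xp = x.pad_time(pad, axis=1) if pad else x
        win = xp.take_windows_strided(k, d, 1, n)  # (B, L, k, C)
        dw = (win * self.dw_weight.reshape(1, 1, k, c)).sum(axis=2)
        return self.pw(dw)


class BatchNorm1d(Module):
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, n_channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(n_channels, dtype=DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(n_channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(n_channels, dtype=DTYPE)
        self.running_var = np.ones(n_channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        axes = tuple(range(x.ndim - 1))  # all but channels
        if self.training:
            mu = x.mean(axis=axes, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=axes, keepdims=True)
            inv = (var + self.eps) ** -0.5
            m = self.momentum
            self.running_mean = (
                (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            ).astype(DTYPE)
            self.running_var = (
                (1 - m) * self.running_var + m * var.data.reshape(-1)
            ).astype(DTYPE)
            return xc * inv * self.gamma + self.beta
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        return (x - self.running_mean) * inv * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(x.data.dtype) / keep
        return x * mask


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Squeeze = global average over time, excitation = bottleneck MLP with
    sigmoid gates in (0, 1); the input is rescaled channelwise.  The squeeze
    pools over the whole window, so the gate is a global (non-causal)
    per-channel scalar.
    """

    def __init__(self, n_channels: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        hidden = max(1, n_channels // reduction)
        self.fc1 = Linear(n_channels, hidden, rng)
        self.fc2 = Linear(hidden, n_channels, rng)

    def gates(self, x: Tensor) -> Tensor:
        z = x.mean(axis=1, keepdims=True)  # (B, 1, C)
        return self.fc2(self.fc1(z).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return x * self.gates(x)


class MultiHeadSelfAttention(Module):
    """Standard multi-head scaled-dot-product self-attention (B, L, D)."""

    def __init__(self, d_total: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_total % n_heads:
            raise ValueError(f"d_total={d_total} not divisible by n_heads={n_heads}")
        self.d_total, self.n_heads = d_total, n_heads
        self.d_head = d_total // n_heads
        self.wq = Linear(d_total, d_total, rng)
        self.wk = Linear(d_total, d_total, rng)
        self.wv = Linear(d_total, d_total, rng)
        self.wo = Linear(d_total, d_total, rng)

    def forward(self, x: Tensor, return_weights: bool = False):
        b, l, d = x.shape
        h, dh = self.n_heads, self.d_head

        def split(t: Tensor) -> Tensor:
            return t.reshape(b, l, h, dh).transpose(0, 2, 1, 3)  # (B, H, L, dh)

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))
        attn = scores.softmax(axis=-1)
        ctx = attn @ v  # (B, H, L, dh)
        out = ctx.transpose(0, 2, 1, 3).reshape(b, l, d)
        out = self.wo(out)
        if return_weights:
            return out, attn.data
        return out
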