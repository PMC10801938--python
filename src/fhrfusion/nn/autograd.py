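"""A small reverse-mode automatic-differentiation engine over numpy arrays.

Just enough surface for the signal backbone and attention fusion: broadcast
arithmetic, (batched) matmul, reductions, reshaping, softmax, padding and a
window-gather primitive that expresses dilated causal convolution as a
matmul.  Gradients are accumulated into ``.grad`` by :meth:`Tensor.backward`
via topological traversal.  Float32 is the working dtype for model tensors;
the engine itself is dtype-agnostic (gradient checks run in float64).
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "concat", "cross_entropy_with_logits", "no_grad"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False, parents=(), bwd=None):
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        if _GRAD_ENABLED:
            self.requires_grad = requires_grad or any(
                p.requires_grad for p in parents
            )
        else:
            self.requires_grad = False
        self._parents = parents if self.requires_grad else ()
        self._bwd = bwd

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- backward ------------------------------------------------------------

    def backward(self, grad=None, free_graph: bool = True) -> None:
        """Accumulate gradients into the graph's leaves.

        ``free_graph`` drops the intermediate graph afterwards (breaking the
        closure references) so training loops release memory promptly.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient needs a scalar")
            grad = np.ones_like(self.data)
        topo: list = []
        seen = set()
        stack = [(self, False)]
        while stack:
            t, processed = stack.pop()
            if processed:
                topo.append(t)
                continue
            if id(t) in seen or not t.requires_grad:
                continue
            seen.add(id(t))
            stack.append((t, True))
            for p in t._parents:
                stack.append((p, False))
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._bwd is not None and t.grad is not None:
                t._bwd(t.grad)
        if free_graph:
            for t in topo:
                if t._bwd is not None:  # interior node: not a leaf parameter
                    t._parents = ()
                    t._bwd = None
                    t.grad = None

    def _accumulate(self, g: np.ndarray, fresh: bool = False) -> None:
        # ``fresh`` promises g is a newly allocated array owned by the
        # caller, so it can be stored without a defensive copy.
        if not self.requires_grad:
            return
        if self.grad is None:
            if fresh:
                self.grad = g
            else:
                self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad += g

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        if isinstance(other, (int, float)):
            a, c = self, other
            out = Tensor(a.data + c, parents=(a,))
            out._bwd = lambda g: a._accumulate(g)
            return out
        a, b = self, Tensor.as_tensor(other)
        out = Tensor(a.data + b.data, parents=(a, b))

        def bwd(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        out._bwd = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        a = self
        out = Tensor(-a.data, parents=(a,))
        out._bwd = lambda g: a._accumulate(-g, fresh=True)
        return out

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            a, c = self, other
            out = Tensor(a.data * c, parents=(a,))
            out._bwd = lambda g: a._accumulate(g * c, fresh=True)
            return out
        a, b = self, Tensor.as_tensor(other)
        out = Tensor(a.data * b.data, parents=(a, b))

        def bwd(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape), fresh=True)
            b._accumulate(_unbroadcast(g * a.data, b.data.shape), fresh=True)

        out._bwd = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self**-1.0

    def __pow__(self, p: float):
        a = self
        out = Tensor(a.data**p, parents=(a,))
        out._bwd = lambda g: a._accumulate(g * p * a.data ** (p - 1), fresh=True)
        return out

    def __matmul__(self, other):
        a, b = self, Tensor.as_tensor(other)
        out = Tensor(a.data @ b.data, parents=(a, b))

        def bwd(g):
            a._accumulate(
                _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape), fresh=True
            )
            b._accumulate(
                _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape), fresh=True
            )

        out._bwd = bwd
        return out

    # -- elementwise nonlinearities ------------------------------------------

    def exp(self):
        a = self
        y = np.exp(a.data)
        out = Tensor(y, parents=(a,))
        out._bwd = lambda g: a._accumulate(g * y, fresh=True)
        return out

    def log(self):
        a = self
        out = Tensor(np.log(a.data), parents=(a,))
        out._bwd = lambda g: a._accumulate(g / a.data, fresh=True)
        return out

    def sqrt(self):
        return self**0.5

    def relu(self):
        a = self
        mask = a.data > 0
        out = Tensor(a.data * mask, parents=(a,))
        out._bwd = lambda g: a._accumulate(g * mask, fresh=True)
        return out

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))
        out = Tensor(y, parents=(a,))
        out._bwd = lambda g: a._accumulate(g * y * (1.0 - y), fresh=True)
        return out

    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(y, parents=(a,))

        def bwd(g):
            dot = (g * y).sum(axis=axis, keepdims=True)
            a._accumulate(y * (g - dot), fresh=True)

        out._bwd = bwd
        return out

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

        def bwd(g):
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.data.shape).copy(), fresh=True)
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape).copy(), fresh=True)

        out._bwd = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            n = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        a = self
        idx = a.data.argmax(axis=axis)
        val = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
        out_data = val if keepdims else np.squeeze(val, axis=axis)
        out = Tensor(out_data, parents=(a,))

        def bwd(g):
            ga = np.zeros_like(a.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(ga, np.expand_dims(idx, axis), gg, axis=axis)
            a._accumulate(ga, fresh=True)

        out._bwd = bwd
        return out

    # -- shape ops -----------------------------------------------------------

    def reshape(self, *shape):
        a = self
        out = Tensor(a.data.reshape(*shape), parents=(a,))
        out._bwd = lambda g: a._accumulate(g.reshape(a.data.shape))
        return out

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)
        out = Tensor(a.data.transpose(*axes), parents=(a,))
        out._bwd = lambda g: a._accumulate(g.transpose(*inv))
        return out

    def pad_time(self, left: int, axis: int = 1):
        """Zero-pad ``left`` positions at the start of the given axis."""
        a = self
        pad = [(0, 0)] * a.data.ndim
        pad[axis] = (left, 0)
        out = Tensor(np.pad(a.data, pad), parents=(a,))
        sl = [slice(None)] * a.data.ndim
        sl[axis] = slice(left, None)
        out._bwd = lambda g: a._accumulate(np.ascontiguousarray(g[tuple(sl)]), fresh=True)
        return out

    def take_windows(self, idx: np.ndarray):
        """Gather time windows: (B, L, C) x (Lout, k) -> (B, Lout, k, C)."""
        a = self
        out = Tensor(a.data[:, idx, :], parents=(a,))

        def bwd(g):
            ga = np.zeros_like(a.data)
            flat = idx.ravel()
            np.add.at(
                ga,
                (slice(None), flat),
                g.reshape(g.shape[0], -1, g.shape[-1]),
            )
            a._accumulate(ga, fresh=True)

        out._bwd = bwd
        return out

    def take_windows_strided(self, k: int, dilation: int, stride: int, n_out: int):
        """Gather conv windows from a left-padded (B, Lp, C) sequence.

        Window t holds positions t*stride + dilation*j for j = 0..k-1
        (oldest tap first); output (B, n_out, k, C).  The backward pass
        scatter-adds one strided slice per tap, which is far cheaper than a
        general fancy-index scatter.
        """
        a = self
        idx = (np.arange(n_out) * stride)[:, None] + dilation * np.arange(k)[None, :]
        out = Tensor(a.data[:, idx, :], parents=(a,))

        def bwd(g):
            ga = np.zeros_like(a.data)
            for j in range(k):
                sl = slice(j * dilation, j * dilation + n_out * stride, stride)
                ga[:, sl, :] += g[:, :, j, :]
            a._accumulate(ga, fresh=True)

        out._bwd = bwd
        return out

    def slice_time(self, sl: slice, axis: int = 1):
        a = self
        index = [slice(None)] * a.data.ndim
        index[axis] = sl
        index = tuple(index)
        out = Tensor(a.data[index], parents=(a,))

        def bwd(g):
            ga = np.zeros_like(a.data)
            ga[index] = g
            a._accumulate(ga, fresh=True)

        out._bwd = bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(int(a), int(b))
            t._accumulate(g[tuple(sl)])

    out._bwd = bwd
    return out


def cross_entropy_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets under softmax(logits)."""
    z = logits.data
    zmax = z.max(axis=1, keepdims=True)
    logsumexp = zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n = z.shape[0]
    loss_val = -logp[np.arange(n), targets].mean()
    out = Tensor(np.asarray(loss_val, dtype=z.dtype), parents=(logits,))

    def bwd(g):
        probs = np.exp(logp)
        probs[np.arange(n), targets] -= 1.0
        logits._accumulate(g * probs / n, fresh=True)

    out._bwd = bwd
    return out
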