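"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps a float32 ndarray
and records, for every differentiable operation, a closure that maps the
output gradient back onto the operands.  ``backward()`` runs a topological
sweep over the recorded graph.  Only the operations the network needs are
provided (elementwise arithmetic, two-operand einsum, im2col unfolding for
convolutions, window max for pooling, axis reductions, shape surgery).

Gradient correctness for every primitive is checked against central finite
differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "as_tensor",
    "concatenate",
    "einsum2",
    "unfold",
    "max_pool2d",
    "softmax",
    "log_softmax",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (evaluation mode / inference)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting).

    Returns ``grad`` itself (no copy, no view) when no reduction is needed,
    so callers can tell whether the result shares the input buffer.
    """
    if grad.shape == tuple(shape):
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _result(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, grad: np.ndarray, fresh: bool = False) -> None:
        """Add ``grad`` into this tensor's gradient buffer.

        ``fresh=True`` promises the caller created ``grad`` solely for this
        call (a new writable array no other tensor will receive), letting
        us adopt it without the defensive copy.  Closures that may pass a
        shared buffer or a read-only/view array must leave it False.
        """
        if self.grad is None:
            if fresh and grad.dtype == np.float32:
                self.grad = grad
            else:
                self.grad = np.array(grad, dtype=np.float32)
        else:
            self.grad += grad

    # -- core properties ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- backward sweep -------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow recursion limits
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/graph so big training loops stay lean
                if node is not self:
                    node.grad = None
                node._backward = None
                node._parents = ()

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = _unbroadcast(g, a.shape)
                a._accumulate(ga, fresh=ga is not g)
            if b.requires_grad:
                gb = _unbroadcast(g, b.shape)
                b._accumulate(gb, fresh=gb is not g)

        return Tensor._result(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accumulate(-g, fresh=True)

        return Tensor._result(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape), fresh=True)
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape), fresh=True)

        return Tensor._result(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other).power(-1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * self.power(-1.0)

    def power(self, p: float) -> "Tensor":
        a = self
        out_data = a.data**p

        def bw(g):
            a._accumulate(g * p * a.data ** (p - 1.0), fresh=True)

        return Tensor._result(out_data, (a,), bw)

    def __pow__(self, p):
        return self.power(float(p))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accumulate(_unbroadcast(ga, a.shape), fresh=True)
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape), fresh=True)

        return Tensor._result(a.data @ b.data, (a, b), bw)

    # -- nonlinearities -------------------------------------------------------
    def relu(self) -> "Tensor":
        a = self
        mask = a.data > 0

        def bw(g):
            a._accumulate(g * mask, fresh=True)

        return Tensor._result(a.data * mask, (a,), bw)

    def sigmoid(self) -> "Tensor":
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accumulate(g * s * (1.0 - s), fresh=True)

        return Tensor._result(s, (a,), bw)

    def tanh(self) -> "Tensor":
        a = self
        t = np.tanh(a.data)

        def bw(g):
            a._accumulate(g * (1.0 - t * t), fresh=True)

        return Tensor._result(t, (a,), bw)

    def exp(self) -> "Tensor":
        a = self
        e = np.exp(a.data)

        def bw(g):
            a._accumulate(g * e, fresh=True)

        return Tensor._result(e, (a,), bw)

    def log(self) -> "Tensor":
        a = self

        def bw(g):
            a._accumulate(g / a.data, fresh=True)

        return Tensor._result(np.log(a.data), (a,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.shape))

        return Tensor._result(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int) -> "Tensor":
        a = self
        idx = np.argmax(a.data, axis=axis)
        out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
        out_data = np.squeeze(out_data, axis=axis)

        def bw(g):
            ga = np.zeros_like(a.data)
            np.put_along_axis(
                ga, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            a._accumulate(ga, fresh=True)

        return Tensor._result(out_data, (a,), bw)

    # -- shape surgery --------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            a._accumulate(np.ascontiguousarray(g.reshape(old)), fresh=True)

        return Tensor._result(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def bw(g):
            a._accumulate(g.transpose(inv), fresh=False)

        return Tensor._result(a.data.transpose(axes), (a,), bw)

    def __getitem__(self, key) -> "Tensor":
        a = self
        parts = key if isinstance(key, tuple) else (key,)
        advanced = any(isinstance(p, (np.ndarray, list)) for p in parts)

        def bw(g):
            ga = np.zeros_like(a.data)
            if advanced:  # duplicate indices must accumulate
                np.add.at(ga, key, g)
            else:
                ga[key] += g
            a._accumulate(ga, fresh=True)

        return Tensor._result(a.data[key], (a,), bw)

    def pad2d(self, pad: int, value: float = 0.0) -> "Tensor":
        """Pad the two trailing spatial axes symmetrically by ``pad``."""
        if pad == 0:
            return self
        a = self
        width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
        data = np.pad(a.data, width, constant_values=value)
        sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))

        def bw(g):
            a._accumulate(np.ascontiguousarray(g[sl]), fresh=True)

        return Tensor._result(data, (a,), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(lo), int(hi))
                t._accumulate(np.ascontiguousarray(g[tuple(sl)]), fresh=True)

    data = np.concatenate([t.data for t in tensors], axis=axis)
    return Tensor._result(data, tensors, bw)


def einsum2(spec: str, a: Tensor, b: Tensor) -> Tensor:
    """Two-operand einsum with reverse-mode gradients.

    Every index of each operand must also appear in the output or in the
    other operand (true for all contractions used here), so each gradient
    is itself a two-operand einsum.
    """
    a, b = as_tensor(a), as_tensor(b)
    ins, s_out = spec.split("->")
    s_a, s_b = ins.split(",")
    known = set(s_out)
    if not (set(s_a) <= known | set(s_b) and set(s_b) <= known | set(s_a)):
        raise ValueError(f"unsupported einsum spec for autodiff: {spec}")

    def bw(g):
        if a.requires_grad:
            a._accumulate(
                np.einsum(f"{s_out},{s_b}->{s_a}", g, b.data, optimize=True),
                fresh=True,
            )
        if b.requires_grad:
            b._accumulate(
                np.einsum(f"{s_out},{s_a}->{s_b}", g, a.data, optimize=True),
                fresh=True,
            )

    data = np.einsum(spec, a.data, b.data, optimize=True)
    return Tensor._result(data, (a, b), bw)


# -- im2col / col2im ---------------------------------------------------------


def _out_hw(h: int, w: int, k: int, stride: int, padding: int) -> tuple[int, int]:
    return (h + 2 * padding - k) // stride + 1, (w + 2 * padding - k) // stride + 1


def _unfold_np(x: np.ndarray, k: int, stride: int, padding: int) -> np.ndarray:
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho, wo = _out_hw(h, w, k, stride, padding)
    v = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    v = v[:, :, ::stride, ::stride]  # N,C,Ho,Wo,k,k
    return np.ascontiguousarray(v.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, ho * wo
    )


def _fold_np(
    cols: np.ndarray, x_shape: tuple, k: int, stride: int, padding: int
) -> np.ndarray:
    """Scatter-add columns back onto the input grid (adjoint of unfold)."""
    n, c, h, w = x_shape
    ho, wo = _out_hw(h, w, k, stride, padding)
    hp, wp = h + 2 * padding, w + 2 * padding
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols[:, :, i, j]
            )
    if padding:
        out = out[:, :, padding:-padding, padding:-padding]
    return out


def group_norm(
    x: Tensor, gamma: Tensor, beta: Tensor, groups: int, eps: float = 1e-5
) -> Tensor:
    """Fused group normalization with affine, N×C×... layout.

    One graph node instead of the ~ten a composite implementation needs;
    the backward pass uses the standard normalization gradient
    dx = (dxhat − mean(dxhat) − xhat·mean(dxhat·xhat)) / σ per group.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c = x.shape[0], x.shape[1]
    spatial = x.shape[2:]
    xg = x.data.reshape(n, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xg - mu) * inv  # N,G,M
    aff_shape = (1, c) + (1,) * len(spatial)
    out = xhat.reshape(x.shape) * gamma.data.reshape(aff_shape) + beta.data.reshape(
        aff_shape
    )

    def bw(g):
        red = tuple([0] + list(range(2, 2 + len(spatial))))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=red), fresh=True)
        xhat_full = xhat.reshape(x.shape)
        if gamma.requires_grad:
            gamma._accumulate((g * xhat_full).sum(axis=red), fresh=True)
        if x.requires_grad:
            dxhat = (g * gamma.data.reshape(aff_shape)).reshape(n, groups, -1)
            m1 = dxhat.mean(axis=2, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=2, keepdims=True)
            dx = (dxhat - m1 - xhat * m2) * inv
            x._accumulate(dx.reshape(x.shape))

    return Tensor._result(out, (x, gamma, beta), bw)


def unfold(x: Tensor, k: int, stride: int = 1, padding: int = 0) -> Tensor:
    """im2col: N×C×H×W → N×(C·k·k)×L with L = Ho·Wo."""
    a = as_tensor(x)
    shape = a.shape

    def bw(g):
        a._accumulate(_fold_np(g, shape, k, stride, padding), fresh=True)

    return Tensor._result(_unfold_np(a.data, k, stride, padding), (a,), bw)


def max_pool2d(x: Tensor, k: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    """Window max with -inf padding so borders never prefer the pad value."""
    a = as_tensor(x)
    n, c, h, w = a.shape
    ho, wo = _out_hw(h, w, k, stride, padding)
    xp = a.data
    if padding:
        xp = np.pad(
            xp,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    v = v[:, :, ::stride, ::stride].reshape(n, c, ho, wo, k * k)
    idx = np.argmax(v, axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        cols = np.zeros((n, c, ho, wo, k * k), dtype=g.dtype)
        np.put_along_axis(cols, idx[..., None], g[..., None], axis=-1)
        cols = cols.transpose(0, 1, 4, 2, 3).reshape(n, c * k * k, ho * wo)
        a._accumulate(_fold_np(cols, (n, c, h, w), k, stride, padding), fresh=True)

    return Tensor._result(np.ascontiguousarray(out_data), (a,), bw)


# -- composite helpers -------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x - np.max(x.data, axis=axis, keepdims=True)  # detached constant
    e = shift.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    shift = x - np.max(x.data, axis=axis, keepdims=True)
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()
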