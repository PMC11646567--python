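"""Minimal reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
recorded tape.  Only the operations the affinity model needs are provided
(broadcasted arithmetic, 2-D matmul, row softmax with optional key masks,
layer normalization, same-padded 1-D convolution, gather/scatter indexing).
Everything is float64 for reproducibility across platforms.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int, Sequence]


def _as_array(x: ArrayLike) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _prev: Iterable["Tensor"] = (),
        name: str = "",
    ):
        self.data = _as_array(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._backward: Optional[Callable[[], None]] = None
        self._prev = tuple(_prev)
        self.name = name

    # -- infrastructure -----------------------------------------------------

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for child in node._prev:
                if id(child) not in seen:
                    stack.append((child, False))
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ---------------------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(fwd(self.data, other.data),
                     requires_grad=self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _backward():
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(bwd_self(g, self.data, other.data), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(bwd_other(g, self.data, other.data), other.data.shape))

        out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out._backward = _backward
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data,
                     requires_grad=self.requires_grad or other.requires_grad,
                     _prev=(self, other))

        def _backward():
            g = out.grad
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = _backward
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.T)

        out._backward = _backward
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.data.shape))

        out._backward = _backward
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = _backward
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)

    # -- nonlinearities -----------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        out._backward = _backward
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, slope * self.data),
                     self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * np.where(self.data > 0, 1.0, slope))

        out._backward = _backward
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad, (self,))

        def _backward():
            if self.requires_grad:
                self._accum(out.grad * out.data)

        out._backward = _backward
        return out


# -- composite / structural operations --------------------------------------


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 requires_grad=any(t.requires_grad for t in tensors),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out.grad.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out._backward = _backward
    return out


def softmax_rows(logits: Tensor, mask: Optional[np.ndarray] = None) -> Tensor:
    """Row-wise softmax over the last axis.

    `mask` (same shape, boolean) marks *allowed* positions; disallowed
    positions get probability exactly 0 and receive no gradient.  A row with
    no allowed position is a caller error.
    """
    z = logits.data
    if mask is not None:
        if not mask.any(axis=-1).all():
            raise ValueError("softmax row with empty support")
        z = np.where(mask, z, -np.inf)
    z = z - np.max(z, axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, logits.requires_grad, (logits,))

    def _backward():
        if logits.requires_grad:
            g = out.grad
            dot = (g * p).sum(axis=-1, keepdims=True)
            logits._accum(p * (g - dot))

    out._backward = _backward
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalize each row of `x` (last axis) then scale/shift by gamma/beta."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = Tensor(xhat * gamma.data + beta.data,
                 x.requires_grad or gamma.requires_grad or beta.requires_grad,
                 (x, gamma, beta))

    def _backward():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            n = x.data.shape[-1]
            gx = g * gamma.data
            dx = (gx - gx.mean(axis=-1, keepdims=True)
                  - xhat * (gx * xhat).mean(axis=-1, keepdims=True)) * inv
            x._accum(dx)

    out._backward = _backward
    return out


def embedding_lookup(table: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows of `table` (V x d) at integer `indices` (length n)."""
    idx = np.asarray(indices, dtype=np.int64)
    out = Tensor(table.data[idx], table.requires_grad, (table,))

    def _backward():
        if table.requires_grad:
            g = np.zeros_like(table.data)
            np.add.at(g, idx, out.grad)
            table._accum(g)

    out._backward = _backward
    return out


def conv1d_same(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None) -> Tensor:
    """Same-padded 1-D convolution.

    x: (p, c_in) sequence; weight: (k, c_in, c_out) with odd k; bias: (c_out,).
    The input is zero-padded by (k-1)//2 on each side so the output keeps
    length p.
    """
    p, c_in = x.data.shape
    k, c_in_w, c_out = weight.data.shape
    if c_in_w != c_in:
        raise ValueError("channel mismatch")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd for symmetric same-padding")
    half = (k - 1) // 2
    xp = np.zeros((p + 2 * half, c_in))
    xp[half:half + p] = x.data
    # windows: (p, k, c_in)
    win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=0)  # (p, c_in, k)
    win = win.transpose(0, 2, 1)  # (p, k, c_in)
    y = np.einsum("pkc,kcd->pd", win, weight.data)
    if bias is not None:
        y = y + bias.data
    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(y, any(t.requires_grad for t in prev), prev)

    def _backward():
        g = out.grad  # (p, c_out)
        if weight.requires_grad:
            weight._accum(np.einsum("pkc,pd->kcd", win, g))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=0))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            # dL/dxp[j+t] += g[j] . w[t]
            gwin = np.einsum("pd,kcd->pkc", g, weight.data)
            for t in range(k):
                gxp[t:t + p] += gwin[:, t, :]
            x._accum(gxp[half:half + p])

    out._backward = _backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep) / keep
    out = Tensor(x.data * mask, x.requires_grad, (x,))

    def _backward():
        if x.requires_grad:
            x._accum(out.grad * mask)

    out._backward = _backward
    return out


def mean_rows(x: Tensor) -> Tensor:
    """Arithmetic mean over axis 0 (token pooling)."""
    return x.mean(axis=0)
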