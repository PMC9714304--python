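"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the tagger in :mod:`kiwiner.neural`: elementwise
arithmetic with broadcasting, matrix products, the sigmoid/tanh/exp/log
nonlinearities, reductions, concatenation/stacking/slicing, a stable
log-sum-exp, softmax, and an embedding-style row gather.  Gradients are
accumulated by a topological-order backward sweep from a scalar loss.

Values are float64 throughout; the tagger is small enough that precision is
cheaper than debugging drift, and it keeps same-seed runs bitwise stable.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum *grad* down to *shape* (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        _backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self.grad: Optional[np.ndarray] = None
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- infrastructure ----------------------------------------------------

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this scalar."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            stack = [(t, iter(t._prev))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for child in it:
                    if id(child) not in seen and child.requires_grad:
                        seen.add(id(child))
                        stack.append((child, iter(child._prev)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x: ArrayLike) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other: ArrayLike) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(-g)
        return out

    def __sub__(self, other: ArrayLike) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other: ArrayLike) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other: ArrayLike) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other: ArrayLike) -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        out._backward = bw
        return out

    def __matmul__(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g: np.ndarray) -> None:
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g / self.data)
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * (1 - out.data**2))
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g * out.data * (1 - out.data))
        return out

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.reshape(self.shape))
        return out

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, _prev=(self,))
        out._backward = lambda g: self.requires_grad and self._accum(g.T)
        return out

    def sum(self, axis: Optional[int] = None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g: np.ndarray) -> None:
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self) -> "Tensor":
        return self.sum() / self.data.size


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), _prev=tuple(tensors))

    def bw(g: np.ndarray) -> None:
        parts = np.split(g, len(tensors), axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(np.squeeze(p, axis=axis))

    out._backward = bw
    return out


def rows(matrix: Tensor, idx: Sequence[int]) -> Tensor:
    """Gather rows of a 2-D tensor (embedding lookup); backward scatter-adds."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(matrix.data[idx], _prev=(matrix,))

    def bw(g: np.ndarray) -> None:
        if matrix.requires_grad:
            full = np.zeros_like(matrix.data)
            np.add.at(full, idx, g)
            matrix._accum(full)

    out._backward = bw
    return out


def logsumexp(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along *axis* (max treated as constant)."""
    m = x.data.max(axis=axis, keepdims=True)
    shifted = x - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        new_shape = tuple(
            s for ax, s in enumerate(out.data.shape) if ax != axis % out.data.ndim
        )
        out = out.reshape(new_shape)
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    m = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape))


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data: ArrayLike):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None
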