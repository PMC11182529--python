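"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The models in this package are small (a handful of dense matmuls per
sample), so a lightweight tape-based engine is sufficient and keeps the
dependency footprint to NumPy alone.  Only the operations the encoders
and losses actually need are implemented; all arrays are kept at ndim
>= 2 so matmul broadcasting stays simple.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "constant",
    "concat",
    "relu",
    "sigmoid",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _prev: Sequence["Tensor"] = (),
        _backward: Callable[[np.ndarray], None] | None = None,
    ):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._prev = tuple(_prev)
        self._backward = _backward

    # ------------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph bookkeeping ---------------------------------------------
    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None, free_graph: bool = True) -> None:
        """Backpropagate; by default release the graph afterwards.

        Releasing (clearing each node's parents and backward closure)
        breaks the reference cycles formed by the closures, so the
        intermediate arrays are freed by reference counting instead of
        waiting for the cyclic garbage collector.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        if free_graph:
            for node in topo:
                node._backward = None
                node._prev = ()
                if not node.requires_grad and node is not self:
                    node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    @property
    def _wants(self) -> bool:
        """Whether a gradient must be computed for this node.

        Leaf constants (no parents, requires_grad False) cannot lead to
        a parameter, so backward passes skip them entirely.
        """
        return self.requires_grad or bool(self._prev)

    # -- arithmetic -----------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = _as_tensor(other, like=self)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bwd(g):
            if self._wants:
                self._accumulate(g)
            if other._wants:
                other._accumulate(g)

        out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other) -> "Tensor":
        return self + (-_as_tensor(other, like=self))

    def __rsub__(self, other) -> "Tensor":
        return _as_tensor(other, like=self) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = _as_tensor(other, like=self)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bwd(g):
            if self._wants:
                self._accumulate(g * other.data)
            if other._wants:
                other._accumulate(g * self.data)

        out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = _as_tensor(other, like=self)
        out = Tensor(self.data / other.data, _prev=(self, other))

        def _bwd(g):
            if self._wants:
                self._accumulate(g / other.data)
            if other._wants:
                other._accumulate(-g * self.data / (other.data**2))

        out._backward = _bwd
        return out

    def __rtruediv__(self, other) -> "Tensor":
        return _as_tensor(other, like=self) / self

    def __matmul__(self, other) -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bwd(g):
            if self._wants:
                self._accumulate(g @ np.swapaxes(other.data, -1, -2))
            if other._wants:
                if other.data.ndim == 2 and g.ndim > 2:
                    # (..., m, k) @ (k, n): fold the batch dims so the
                    # weight gradient is one flat matmul, not a batched
                    # product followed by a reduction.
                    k = self.data.shape[-1]
                    n = g.shape[-1]
                    other._accumulate(
                        self.data.reshape(-1, k).T @ g.reshape(-1, n)
                    )
                else:
                    other._accumulate(np.swapaxes(self.data, -1, -2) @ g)

        out._backward = _bwd
        return out

    def __pow__(self, exponent: float) -> "Tensor":
        out = Tensor(self.data**exponent, _prev=(self,))
        out._backward = lambda g: self._accumulate(g * exponent * self.data ** (exponent - 1))
        return out

    # -- reductions / shaping ------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        maxval = self.data.max(axis=axis, keepdims=True)
        out_data = maxval if keepdims else np.squeeze(maxval, axis=axis)
        out = Tensor(out_data, _prev=(self,))
        mask = (self.data == maxval).astype(self.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True)

        def _bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(mask * g)

        out._backward = _bwd
        return out

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose(self, *axes) -> "Tensor":
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes) if axes else None

        def _bwd(g):
            self._accumulate(g.transpose(inv) if inv is not None else g.transpose())

        out._backward = _bwd
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose()

    def take_rows(self, indices: np.ndarray) -> "Tensor":
        """Per-batch row gather: (B, M, F) indexed by (B,) -> (B, F)."""
        idx = np.asarray(indices)
        batch = np.arange(self.data.shape[0])
        out = Tensor(self.data[batch, idx], _prev=(self,))

        def _bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (batch, idx), g)
            self._accumulate(full)

        out._backward = _bwd
        return out

    # -- elementwise nonlinear -----------------------------------------
    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sqrt(self) -> "Tensor":
        return self**0.5

    def clip(self, lo: float, hi: float) -> "Tensor":
        out = Tensor(np.clip(self.data, lo, hi), _prev=(self,))
        inside = ((self.data > lo) & (self.data < hi)).astype(self.data.dtype)
        out._backward = lambda g: self._accumulate(g * inside)
        return out


def _as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if like is not None and np.isscalar(x):
        # keep python scalars from upcasting float32 operands
        return Tensor(np.asarray(x, dtype=like.data.dtype))
    return Tensor(x)


def parameter(data, dtype=np.float32) -> Tensor:
    return Tensor(np.asarray(data, dtype=dtype), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0.0), _prev=(x,))
    mask = (x.data > 0).astype(x.data.dtype)
    out._backward = lambda g: x._accumulate(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable two-branch logistic
    d = x.data
    pos = d >= 0
    z = np.empty_like(d)
    z[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    ez = np.exp(d[~pos])
    z[~pos] = ez / (1.0 + ez)
    out = Tensor(z, _prev=(x,))
    out._backward = lambda g: x._accumulate(g * out.data * (1.0 - out.data))
    return out


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t._wants:
                t._accumulate(piece)

    out._backward = _bwd
    return out


class Adam:
    """Adam optimizer over a flat list of parameter Tensors."""

    def __init__(
        self,
        params: Iterable[Tensor],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
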