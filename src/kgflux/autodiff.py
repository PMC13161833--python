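"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the partitioning network and its
physics losses: dense affine maps, smooth/elementwise nonlinearities,
broadcasting arithmetic, reductions, and inverted dropout. Gradients are
accumulated by topological-order backpropagation from a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "absolute",
    "concat_flat",
    "dropout",
    "exp",
    "mean",
    "relu",
    "sigmoid",
    "softplus",
    "sqrt",
    "square",
    "sum_",
    "tanh",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast up from `shape`."""
    if grad.shape == shape:
        return grad
    # sum over leading extra dims
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make `ndarray <op> Tensor` defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd engine ------------------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this scalar tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        # clear stale gradients from any earlier backward over a shared graph
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad, dtype=np.float64), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(g)
            other._accum(g)

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data**2)

        return Tensor(self.data / other.data, parents=(self, other), backward=bwd)

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) / self

    def __pow__(self, p: float):
        p = float(p)

        def bwd(g):
            self._accum(g * p * self.data ** (p - 1.0))

        return Tensor(self.data**p, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = Tensor.as_tensor(other)

        def bwd(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)


# -- elementwise functions ----------------------------------------------------
def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def bwd(g):
        x._accum(g * out_data)

    return Tensor(out_data, parents=(x,), backward=bwd)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def bwd(g):
        x._accum(g * 0.5 / out_data)

    return Tensor(out_data, parents=(x,), backward=bwd)


def square(x: Tensor) -> Tensor:
    return x * x


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def bwd(g):
        x._accum(g * (1.0 - out_data**2))

    return Tensor(out_data, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        x._accum(g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(x,), backward=bwd)


def softplus(x: Tensor) -> Tensor:
    """log(1 + exp(x)), numerically stable; derivative is the sigmoid."""
    out_data = np.logaddexp(0.0, x.data)

    def bwd(g):
        x._accum(g / (1.0 + np.exp(-x.data)))

    return Tensor(out_data, parents=(x,), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = (x.data > 0).astype(np.float64)

    def bwd(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bwd)


def absolute(x: Tensor) -> Tensor:
    sign = np.sign(x.data)

    def bwd(g):
        x._accum(g * sign)

    return Tensor(np.abs(x.data), parents=(x,), backward=bwd)


def dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    """Inverted dropout: zeroes a fraction `rate` and rescales the survivors."""
    if rate <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= rate) / (1.0 - rate)

    def bwd(g):
        x._accum(g * keep)

    return Tensor(x.data * keep, parents=(x,), backward=bwd)


# -- reductions ---------------------------------------------------------------
def sum_(x: Tensor) -> Tensor:
    def bwd(g):
        x._accum(np.full(x.data.shape, float(g)))

    return Tensor(x.data.sum(), parents=(x,), backward=bwd)


def mean(x: Tensor) -> Tensor:
    n = x.data.size

    def bwd(g):
        x._accum(np.full(x.data.shape, float(g) / n))

    return Tensor(x.data.mean(), parents=(x,), backward=bwd)


def concat_flat(tensors: list[Tensor]) -> Tensor:
    """Concatenate flattened tensors (used for whole-parameter gradient norms)."""
    datas = [t.data.ravel() for t in tensors]
    sizes = [d.size for d in datas]

    def bwd(g):
        off = 0
        for t, s in zip(tensors, sizes):
            t._accum(g[off : off + s].reshape(t.data.shape))
            off += s

    return Tensor(np.concatenate(datas), parents=tuple(tensors), backward=bwd)
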