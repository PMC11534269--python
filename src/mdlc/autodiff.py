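"""Minimal reverse-mode automatic differentiation over numpy arrays.

The agent's recurrent pathways are trained by backpropagation through time,
so the package carries a small tape-based autodiff engine: a :class:`Tensor`
wraps an ``ndarray`` together with a gradient slot and a closure that
accumulates gradients into its parents.  Only the operations the agent
actually uses are implemented (broadcast arithmetic, matmul, the usual
pointwise nonlinearities, reductions, ``log_softmax`` and fancy-index
gather).  Gradients are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "concat", "no_grad"]


class _NoGrad:
    """Context manager disabling graph construction (evaluation mode)."""

    enabled = False

    def __enter__(self):
        self._prev = _NoGrad.enabled
        _NoGrad.enabled = True
        return self

    def __exit__(self, *exc):
        _NoGrad.enabled = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and not _NoGrad.enabled
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs from BPTT can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data + other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad)
            if other.requires_grad:
                other._accumulate(out.grad)

        out._backward = bw if out.requires_grad else None
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data * other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad * other.data)
            if other.requires_grad:
                other._accumulate(out.grad * self.data)

        out._backward = bw if out.requires_grad else None
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = _as_tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, requires_grad=self.requires_grad, parents=(self,))

        def bw():
            self._accumulate(out.grad * p * self.data ** (p - 1.0))

        out._backward = bw if out.requires_grad else None
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(
            self.data @ other.data,
            requires_grad=self.requires_grad or other.requires_grad,
            parents=(self, other),
        )

        def bw():
            if self.requires_grad:
                self._accumulate(out.grad @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ out.grad)

        out._backward = bw if out.requires_grad else None
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], requires_grad=self.requires_grad, parents=(self,))

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accumulate(g)

        out._backward = bw if out.requires_grad else None
        return out

    # -- pointwise nonlinearities -------------------------------------------
    def exp(self):
        out = Tensor(np.exp(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw():
            self._accumulate(out.grad * out.data)

        out._backward = bw if out.requires_grad else None
        return out

    def log(self):
        out = Tensor(np.log(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw():
            self._accumulate(out.grad / self.data)

        out._backward = bw if out.requires_grad else None
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw():
            self._accumulate(out.grad * (1.0 - out.data ** 2))

        out._backward = bw if out.requires_grad else None
        return out

    def sigmoid(self):
        out = Tensor(
            1.0 / (1.0 + np.exp(-self.data)),
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def bw():
            self._accumulate(out.grad * out.data * (1.0 - out.data))

        out._backward = bw if out.requires_grad else None
        return out

    def sqrt(self):
        return self ** 0.5

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), requires_grad=self.requires_grad, parents=(self,))

        def bw():
            self._accumulate(out.grad * sign)

        out._backward = bw if out.requires_grad else None
        return out

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(
            self.data.sum(axis=axis, keepdims=keepdims),
            requires_grad=self.requires_grad,
            parents=(self,),
        )

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw if out.requires_grad else None
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- composite ops used by the agent --------------------------------------
    def log_softmax(self, axis: int = -1):
        """Numerically stable log-softmax along ``axis``."""
        m = self.data.max(axis=axis, keepdims=True)  # constant shift, no grad needed
        shifted = self - Tensor(m)
        lse = shifted.exp().sum(axis=axis, keepdims=True).log()
        return shifted - lse

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    def take_along(self, indices: np.ndarray):
        """Row-wise gather: ``out[i] = self[i, indices[i]]`` for 2-D tensors."""
        rows = np.arange(self.data.shape[0])
        return self[(rows, np.asarray(indices))]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(
        np.concatenate(datas, axis=axis),
        requires_grad=any(t.requires_grad for t in tensors),
        parents=tuple(tensors),
    )

    def bw():
        splits = np.cumsum([d.shape[axis] for d in datas])[:-1]
        grads = np.split(out.grad, splits, axis=axis)
        for t, g in zip(tensors, grads):
            if t.requires_grad:
                t._accumulate(g)

    out._backward = bw if out.requires_grad else None
    return out
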