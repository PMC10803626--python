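"""Compact reverse-mode automatic differentiation over NumPy arrays.

Supports exactly the operations the graph-attention encoder needs: matrix
multiplication, broadcasting add/multiply, LeakyReLU, a masked row softmax
(for per-node attention normalisation), elementwise square and summation.
Gradients are accumulated by topological-order backpropagation from a
scalar loss; correctness is pinned down by finite-difference checks in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "leaky_relu", "masked_softmax"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape``, inverting NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction --------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            return (_unbroadcast(grad, self.shape), _unbroadcast(grad, other.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            return (_unbroadcast(grad, self.shape), _unbroadcast(-grad, other.shape))

        return Tensor(self.data - other.data, parents=(self, other), backward=backward)

    def __mul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            return (_unbroadcast(grad * other.data, self.shape),
                    _unbroadcast(grad * self.data, other.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._lift(other)

        def backward(grad, out):
            return (grad @ other.data.T, self.data.T @ grad)

        return Tensor(self.data @ other.data, parents=(self, other), backward=backward)

    @property
    def T(self) -> "Tensor":
        def backward(grad, out):
            return (grad.T,)

        return Tensor(self.data.T, parents=(self,), backward=backward)

    def square(self) -> "Tensor":
        def backward(grad, out):
            return (2.0 * self.data * grad,)

        return Tensor(self.data ** 2, parents=(self,), backward=backward)

    def sum(self) -> "Tensor":
        def backward(grad, out):
            return (np.broadcast_to(grad, self.shape).copy(),)

        return Tensor(self.data.sum(), parents=(self,), backward=backward)

    def mean_over(self, others: list["Tensor"]) -> "Tensor":
        """Element-wise mean of self and ``others`` (all same shape)."""
        terms = [self] + list(others)
        k = float(len(terms))

        def backward(grad, out):
            return tuple(grad / k for _ in terms)

        data = sum(t.data for t in terms) / k
        return Tensor(data, parents=tuple(terms), backward=backward)

    # -- backpropagation -----------------------------------------------------

    def backward(self) -> None:
        if self.data.shape != ():
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones(())
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad, node)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros(parent.shape)
                parent.grad = parent.grad + g

    def zero_grad(self) -> None:
        self.grad = None


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data > 0

    def backward(grad, out):
        return (grad * np.where(mask, 1.0, slope),)

    return Tensor(np.where(mask, x.data, slope * x.data), parents=(x,), backward=backward)


def masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax over entries where ``mask`` is True; zeros elsewhere.

    Rows with no unmasked entry come out all-zero. Gradient flows only
    through unmasked positions.
    """
    neg = np.where(mask, logits.data, -np.inf)
    row_max = np.max(neg, axis=1, keepdims=True)
    row_max = np.where(np.isfinite(row_max), row_max, 0.0)
    ex = np.exp(neg - row_max)
    ex = np.where(mask, ex, 0.0)
    denom = ex.sum(axis=1, keepdims=True)
    denom = np.where(denom == 0, 1.0, denom)
    sm = ex / denom

    def backward(grad, out):
        dot = (grad * sm).sum(axis=1, keepdims=True)
        g = sm * (grad - dot)
        return (np.where(mask, g, 0.0),)

    return Tensor(sm, parents=(logits,), backward=backward)


class Adam:
    """Adam optimiser over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros(p.shape) for p in self.params]
        self.v = [np.zeros(p.shape) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
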