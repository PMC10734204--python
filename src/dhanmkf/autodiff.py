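"""Minimal reverse-mode automatic differentiation on numpy arrays.

The attention encoders are small (tens of parameters tensors, graphs of a
few thousand edges), so a tape of closures over numpy ops is sufficient and
keeps the package dependency-free.  Supported operations are exactly those
the encoders and the kernel/loss pipeline need: broadcast arithmetic,
matmul, row gather, segment softmax/sum (per-node attention normalization),
LeakyReLU, exp, power, sigmoid, concat and reductions.  Gradients are
checked against central differences in the test suite.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce *grad* back to *shape* after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_bwd")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._bwd: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents, bwd) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._bwd = bwd
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            stack = [(t, False)]
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

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._bwd is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._bwd(g)):
                if pg is None or not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    # -- operations --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)),
        )

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other) -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other) -> "Tensor":
        return as_tensor(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        return self * as_tensor(other) ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out = self.data**exponent
        return Tensor._make(
            out, (self,), lambda g: (g * exponent * self.data ** (exponent - 1.0),)
        )

    def __matmul__(self, other) -> "Tensor":
        other = as_tensor(other)
        return Tensor._make(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    @property
    def T(self) -> "Tensor":
        return Tensor._make(self.data.T, (self,), lambda g: (g.T,))

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g: np.ndarray):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._make(out, (self,), bwd)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def sigmoid(self) -> "Tensor":
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.int64)

        def bwd(g: np.ndarray):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), bwd)

    def reshape(self, *shape: int) -> "Tensor":
        old = self.shape
        return Tensor._make(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),)
        )


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def stack_mean(tensors: Sequence[Tensor]) -> Tensor:
    """Elementwise mean of same-shape tensors (multi-head averaging)."""
    acc = tensors[0]
    for t in tensors[1:]:
        acc = acc + t
    return acc * (1.0 / len(tensors))


def segment_softmax(scores: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of a flat score vector within each segment.

    Used for attention normalization: ``segments[e]`` is the destination
    node of edge *e*, so coefficients over each node's edge set sum to 1.
    """
    segments = np.asarray(segments, dtype=np.int64)
    maxs = np.full(num_segments, -np.inf)
    np.maximum.at(maxs, segments, scores.data)
    shifted = scores.data - maxs[segments]
    ex = np.exp(shifted)
    sums = np.zeros(num_segments)
    np.add.at(sums, segments, ex)
    out = ex / sums[segments]

    def bwd(g: np.ndarray):
        dot = np.zeros(num_segments)
        np.add.at(dot, segments, out * g)
        return (out * (g - dot[segments]),)

    return Tensor._make(out, (scores,), bwd)


def segment_sum(values: Tensor, segments: np.ndarray, num_segments: int) -> Tensor:
    """Sum edge-wise rows into their segment (node) slots."""
    segments = np.asarray(segments, dtype=np.int64)
    out = np.zeros((num_segments,) + values.shape[1:])
    np.add.at(out, segments, values.data)
    return Tensor._make(out, (values,), lambda g: (g[segments],))


def layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row layer normalization with learnable gain and bias."""
    mu = x.mean(axis=1, keepdims=True)
    centered = x - mu
    var = (centered**2.0).mean(axis=1, keepdims=True)
    inv = (var + eps) ** -0.5
    return centered * inv * gain + bias


class Adam:
    """Adam with additive (L2) weight decay, mirroring the common default."""

    def __init__(
        self,
        params: dict[str, Tensor],
        lr: float = 0.05,
        weight_decay: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
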