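"""Minimal reverse-mode automatic differentiation on numpy arrays.

Only the operations the model zoo needs are implemented; every op builds a
node in a dynamic graph and :meth:`Tensor.backward` runs a topological
sweep accumulating gradients into leaf tensors' ``grad`` attributes.
Gradients are exact (checked against numeric differentiation in the test
suite), broadcasting is supported for elementwise ops.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward_fn")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad: np.ndarray | None = None
        self._parents = tuple(parents)
        self._backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph traversal ----------------------------------------------------

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward_fn is not None:
                for parent, pg in zip(node._parents, node._backward_fn(g)):
                    if pg is None or not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            elif node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g

    # -- operator sugar -----------------------------------------------------

    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


# -- elementwise ------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        parents=(a, b),
        backward_fn=lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(a, b),
        backward_fn=lambda g: (
            _unbroadcast(g * b.data, a.shape),
            _unbroadcast(g * a.data, b.shape),
        ),
    )


def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return Tensor(x.data * mask, parents=(x,), backward_fn=lambda g: (g * mask,))


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(s, parents=(x,), backward_fn=lambda g: (g * s * (1 - s),))


def tanh(x) -> Tensor:
    x = as_tensor(x)
    t = np.tanh(x.data)
    return Tensor(t, parents=(x,), backward_fn=lambda g: (g * (1 - t * t),))


def softplus(x) -> Tensor:
    x = as_tensor(x)
    out = np.logaddexp(0.0, x.data)
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    return Tensor(out, parents=(x,), backward_fn=lambda g: (g * s,))


# -- linear algebra / structure ---------------------------------------------


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data @ b.data,
        parents=(a, b),
        backward_fn=lambda g: (g @ b.data.T, a.data.T @ g),
    )


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors),
        backward_fn=backward,
    )


def slice_cols(x, start: int, stop: int) -> Tensor:
    x = as_tensor(x)

    def backward(g):
        out = np.zeros_like(x.data)
        out[:, start:stop] = g
        return (out,)

    return Tensor(x.data[:, start:stop], parents=(x,), backward_fn=backward)


def gather_rows(table, index) -> Tensor:
    """Row lookup (embedding); gradient scatter-adds into the table."""
    table = as_tensor(table)
    index = np.asarray(index, dtype=int)

    def backward(g):
        out = np.zeros_like(table.data)
        np.add.at(out, index, g)
        return (out,)

    return Tensor(table.data[index], parents=(table,), backward_fn=backward)


def segment_sum(x, segment_ids, n_segments: int) -> Tensor:
    """Sum rows of ``x`` into ``n_segments`` buckets (scatter-add)."""
    x = as_tensor(x)
    segment_ids = np.asarray(segment_ids, dtype=int)
    out = np.zeros((n_segments, x.data.shape[1]))
    np.add.at(out, segment_ids, x.data)
    return Tensor(out, parents=(x,), backward_fn=lambda g: (g[segment_ids],))


def mean_all(x) -> Tensor:
    x = as_tensor(x)
    n = x.data.size
    return Tensor(
        x.data.mean(), parents=(x,), backward_fn=lambda g: (np.full(x.shape, g / n),)
    )


def dropout(x, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    x = as_tensor(x)
    if not training or rate <= 0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return mul(x, Tensor(mask))


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits: mean(softplus(z) - y*z)."""
    y = np.asarray(targets, dtype=float).reshape(logits.shape)
    return mean_all(softplus(logits) - mul(logits, Tensor(y)))
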