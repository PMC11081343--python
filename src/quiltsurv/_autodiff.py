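"""Minimal reverse-mode automatic differentiation over numpy float64 arrays.

The variational fitting loop only ever needs the gradient of a scalar joint
log-density with respect to one flat latent vector, so the engine is a small
tape of :class:`Tensor` nodes supporting exactly the operations the model
density uses: broadcasting arithmetic, matmul, reductions, the logistic /
softplus / log family, gathers by integer index, slicing, reshape, concat and
cumsum.  Every public helper dispatches on its argument type, so model code
written against this module runs unchanged on plain numpy arrays (fast,
gradient-free evaluation) and on tensors (when a gradient is required).

Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "value_of", "exp", "log", "log1p", "sigmoid",
    "softplus", "tsum", "cumsum", "concat", "reshape", "take", "clip_min",
    "square",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("value", "grad", "_parents", "_vjp")

    # make numpy defer to the reflected operators below
    __array_ufunc__ = None

    def __init__(self, value, parents=(), vjp=None):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._vjp = vjp  # callable(grad_out) -> tuple of parent grads

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def backward(self):
        """Accumulate d(self)/d(leaf) into .grad for every node in the tape."""
        if self.value.ndim != 0:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, done = stack.pop()
                if done:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p in n._parents:
                    if id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        for n in topo:
            n.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node.grad is None or node._vjp is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None:
                    continue
                # grads are never mutated in place, so plain assignment is safe
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.value + b.value, (a, b), lambda g: (
            _unbroadcast(g, a.value.shape), _unbroadcast(g, b.value.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.value * b.value, (a, b), lambda g: (
            _unbroadcast(g * b.value, a.value.shape),
            _unbroadcast(g * a.value, b.value.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.value / b.value, (a, b), lambda g: (
            _unbroadcast(g / b.value, a.value.shape),
            _unbroadcast(-g * a.value / b.value ** 2, b.value.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents supported")
        a = self
        return Tensor(a.value ** p, (a,),
                      lambda g: (g * p * a.value ** (p - 1),))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        return Tensor(a.value @ b.value, (a, b), lambda g: (
            g @ b.value.T, a.value.T @ g))

    def __rmatmul__(self, other):
        return as_tensor(other) @ self

    def __getitem__(self, idx):
        a = self

        def vjp(g):
            out = np.zeros_like(a.value)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a.value[idx], (a,), vjp)

    def sum(self, axis=None, keepdims=False):
        a = self

        def vjp(g):
            if axis is None:
                return (np.broadcast_to(g, a.value.shape),)
            gg = np.expand_dims(g, axis) if not keepdims else g
            return (np.broadcast_to(gg, a.value.shape),)

        return Tensor(a.value.sum(axis=axis, keepdims=keepdims), (a,), vjp)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        return Tensor(a.value.reshape(shape), (a,),
                      lambda g: (g.reshape(a.value.shape),))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def value_of(x):
    """The underlying ndarray, whether `x` is a Tensor or array-like."""
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)


# -- dispatching elementwise functions ----------------------------------

def exp(x):
    if isinstance(x, Tensor):
        out = np.exp(x.value)
        return Tensor(out, (x,), lambda g: (g * out,))
    return np.exp(x)


def log(x):
    if isinstance(x, Tensor):
        return Tensor(np.log(x.value), (x,), lambda g: (g / x.value,))
    return np.log(x)


def log1p(x):
    if isinstance(x, Tensor):
        return Tensor(np.log1p(x.value), (x,), lambda g: (g / (1.0 + x.value),))
    return np.log1p(x)


def _sigmoid(v):
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def sigmoid(x):
    if isinstance(x, Tensor):
        out = _sigmoid(x.value)
        return Tensor(out, (x,), lambda g: (g * out * (1.0 - out),))
    return _sigmoid(np.asarray(x, dtype=np.float64))


def _softplus(v):
    return np.logaddexp(0.0, v)


def softplus(x):
    """log(1 + e^x), overflow-safe."""
    if isinstance(x, Tensor):
        out = _softplus(x.value)
        return Tensor(out, (x,), lambda g: (g * _sigmoid(x.value),))
    return _softplus(np.asarray(x, dtype=np.float64))


def square(x):
    if isinstance(x, Tensor):
        return x * x
    return np.square(x)


def tsum(x, axis=None, keepdims=False):
    if isinstance(x, Tensor):
        return x.sum(axis=axis, keepdims=keepdims)
    return np.sum(x, axis=axis, keepdims=keepdims)


def cumsum(x, axis=-1):
    if isinstance(x, Tensor):
        a = x

        def vjp(g):
            return (np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis),
                            axis=axis),)

        return Tensor(np.cumsum(a.value, axis=axis), (a,), vjp)
    return np.cumsum(x, axis=axis)


def concat(parts, axis=-1):
    if any(isinstance(p, Tensor) for p in parts):
        parts = [as_tensor(p) for p in parts]
        sizes = [p.value.shape[axis] for p in parts]
        splits = np.cumsum(sizes)[:-1]

        def vjp(g):
            return tuple(np.split(g, splits, axis=axis))

        return Tensor(np.concatenate([p.value for p in parts], axis=axis),
                      tuple(parts), vjp)
    return np.concatenate(parts, axis=axis)


def reshape(x, shape):
    if isinstance(x, Tensor):
        return x.reshape(shape)
    return np.reshape(x, shape)


def take(x, idx):
    """Gather rows along axis 0 with an integer index array."""
    idx = np.asarray(idx)
    if isinstance(x, Tensor):
        a = x

        def vjp(g):
            out = np.zeros_like(a.value)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor(a.value[idx], (a,), vjp)
    return x[idx]


def clip_min(x, lo):
    """max(x, lo); gradient passes only through the unclipped region."""
    if isinstance(x, Tensor):
        mask = (x.value > lo).astype(np.float64)
        return Tensor(np.maximum(x.value, lo), (x,), lambda g: (g * mask,))
    return np.maximum(x, lo)
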