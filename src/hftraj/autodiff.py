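"""Minimal reverse-mode automatic differentiation on numpy arrays.

The recurrent models in this package are small (tens of hidden units, a few
thousand parameters), so a tape-based numpy engine is sufficient to train
them. Only the operations the networks and losses need are implemented:
broadcasting arithmetic, matrix product, the sigmoid/tanh/log/exp/sqrt
nonlinearities, power with a constant exponent, clipping, reductions and
concatenation. Gradients are accumulated by a reverse topological sweep.

Every op also works when handed plain numpy arrays or scalars (it wraps
them as non-differentiable constants), so forward-only code paths share the
exact same implementation as training.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "sigmoid",
    "tanh",
    "log",
    "exp",
    "sqrt",
    "clip",
    "concat",
    "backward",
]


class Tensor:
    """A numpy array plus the tape metadata needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor.__radd__

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(other, mul(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(other, power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, expo):
        return power(self, expo)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward_fn(g):
        return (_unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward_fn)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward_fn(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _make(out_data, (a, b), backward_fn)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward_fn(g):
        return (g @ b.data.T, a.data.T @ g)

    return _make(out_data, (a, b), backward_fn)


def power(a, expo) -> Tensor:
    """Elementwise a**expo for a constant (non-differentiated) exponent."""
    a = as_tensor(a)
    expo = float(expo)
    out_data = a.data ** expo

    def backward_fn(g):
        return (g * expo * a.data ** (expo - 1.0),)

    return _make(out_data, (a,), backward_fn)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    out_data = np.where(
        a.data >= 0,
        1.0 / (1.0 + np.exp(-np.abs(a.data))),
        np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))),
    )

    def backward_fn(g):
        return (g * out_data * (1.0 - out_data),)

    return _make(out_data, (a,), backward_fn)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward_fn(g):
        return (g * (1.0 - out_data ** 2),)

    return _make(out_data, (a,), backward_fn)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward_fn(g):
        return (g / a.data,)

    return _make(out_data, (a,), backward_fn)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward_fn(g):
        return (g * out_data,)

    return _make(out_data, (a,), backward_fn)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def transpose(a) -> Tensor:
    a = as_tensor(a)

    def backward_fn(g):
        return (g.T,)

    return _make(a.data.T, (a,), backward_fn)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through unclamped entries."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward_fn(g):
        return (g * mask,)

    return _make(out_data, (a,), backward_fn)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward_fn(g):
        return tuple(np.split(g, splits, axis=axis))

    return _make(out_data, tuple(tensors), backward_fn)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward_fn(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _make(out_data, (a,), backward_fn)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def backward(loss: Tensor) -> None:
    """Accumulate d(loss)/d(node) into .grad for every reachable tensor."""
    if loss.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
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
            stack.append((p, False))

    loss.grad = np.ones_like(loss.data)
    for node in reversed(topo):
        if node._backward is None or node.grad is None:
            continue
        grads = node._backward(node.grad)
        for parent, g in zip(node._parents, grads):
            if not parent.requires_grad:
                continue
            if parent.grad is None:
                parent.grad = np.zeros_like(parent.data)
            parent.grad += g


class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
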