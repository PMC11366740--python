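"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the sequence model needs: broadcasting
arithmetic, (batched) matrix products, shape manipulation, softmax /
log-softmax, layer normalisation, GELU/sigmoid/tanh nonlinearities,
embedding lookup and row gathering.  Gradients are accumulated into
``Tensor.grad`` by :meth:`Tensor.backward` over the topologically sorted
graph.  Everything is float64; graphs here are small (tens of tokens),
so clarity wins over throughput.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "softmax", "log_softmax", "layer_norm", "gelu", "sigmoid", "tanh",
           "embedding", "gather_rows", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if not p.requires_grad:
                        continue
                    key = id(p)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        return self._make(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        return self._make(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __sub__(self, other):
        other = self._wrap(other)
        return self._make(
            self.data - other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)))

    def __rsub__(self, other):
        return self._wrap(other) - self

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __truediv__(self, other):
        other = self._wrap(other)
        return self._make(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data

        def backward(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return _unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape)

        return self._make(a @ b, (self, other), backward)

    # -- shape ---------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape
        return self._make(self.data.reshape(*shape), (self,),
                          lambda g: (g.reshape(old),))

    def swapaxes(self, a, b):
        return self._make(np.swapaxes(self.data, a, b), (self,),
                          lambda g: (np.swapaxes(g, a, b),))

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            if not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise ---------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    return x._make(y, (x,), lambda g: (g * (1.0 - y ** 2),))


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    return x._make(y, (x,), lambda g: (g * y * (1.0 - y),))


def gelu(x: Tensor) -> Tensor:
    """Tanh-approximation GELU."""
    c = np.sqrt(2.0 / np.pi)
    u = c * (x.data + 0.044715 * x.data ** 3)
    t = np.tanh(u)
    y = 0.5 * x.data * (1.0 + t)

    def backward(g):
        du = c * (1.0 + 3 * 0.044715 * x.data ** 2)
        dy = 0.5 * (1.0 + t) + 0.5 * x.data * (1.0 - t ** 2) * du
        return (g * dy,)

    return x._make(y, (x,), backward)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        return (y * (g - dot),)

    return x._make(y, (x,), backward)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    y = z - lse
    sm = np.exp(y)

    def backward(g):
        return (g - sm * g.sum(axis=axis, keepdims=True),)

    return x._make(y, (x,), backward)


def layer_norm(x: Tensor, eps: float = 1e-6) -> Tensor:
    """Normalise the last axis to zero mean / unit variance (no affine)."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (x.data - mu) * inv

    def backward(g):
        gy = g * inv
        return (gy - gy.mean(axis=-1, keepdims=True)
                - y * inv * ((g * y).mean(axis=-1, keepdims=True)),)

    return x._make(y, (x,), backward)


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` with scatter-add backward."""
    ids = np.asarray(ids, dtype=np.intp)

    def backward(g):
        gw = np.zeros_like(weight.data)
        np.add.at(gw, ids.reshape(-1), g.reshape(-1, weight.data.shape[1]))
        return (gw,)

    return weight._make(weight.data[ids], (weight,), backward)


def gather_rows(x: Tensor, row_idx: np.ndarray, col_idx: np.ndarray) -> Tensor:
    """Pick ``x[row_idx[j], col_idx[j]]`` from a 2-D tensor."""
    row_idx = np.asarray(row_idx, dtype=np.intp)
    col_idx = np.asarray(col_idx, dtype=np.intp)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.add.at(gx, (row_idx, col_idx), g)
        return (gx,)

    return x._make(x.data[row_idx, col_idx], (x,), backward)


def concat(tensors, axis=0) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    out = Tensor(np.concatenate(datas, axis=axis))
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        out._parents = tuple(tensors)
        out._backward = backward
    return out
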