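"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express and train the recurrent/convolutional
classifiers in this package: a :class:`Tensor` wrapping an ndarray, a
tape of parent links, and backward rules for the handful of primitives
the layer stack uses.  Gradients are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    __slots__ = ("data", "grad", "parents", "backward_fn")

    def __init__(self, data, parents=(), backward_fn=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = parents
        self.backward_fn = backward_fn

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative post-order DFS
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.backward_fn is not None and node.grad is not None:
                node.backward_fn(node.grad)

    # convenience operators
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, key):
        return getitem(self, key)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient g down to the given (broadcast-source) shape."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def bwd(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    out.backward_fn = bwd
    return out


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data - b.data, parents=(a, b))

    def bwd(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(-g, b.shape))

    out.backward_fn = bwd
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def bwd(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    out.backward_fn = bwd
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def bwd(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out.backward_fn = bwd
    return out


def tanh(a: Tensor) -> Tensor:
    y = np.tanh(a.data)
    out = Tensor(y, parents=(a,))
    out.backward_fn = lambda g: a._accumulate(g * (1.0 - y * y))
    return out


def sigmoid(a: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60, 60)))
    out = Tensor(y, parents=(a,))
    out.backward_fn = lambda g: a._accumulate(g * y * (1.0 - y))
    return out


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out = Tensor(a.data * mask, parents=(a,))
    out.backward_fn = lambda g: a._accumulate(g * mask)
    return out


def getitem(a: Tensor, key) -> Tensor:
    out = Tensor(a.data[key], parents=(a,))

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, key, g)
        a._accumulate(full)

    out.backward_fn = bwd
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))
    out.backward_fn = lambda g: a._accumulate(g.reshape(a.shape))
    return out


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    out.backward_fn = bwd
    return out


def stack(tensors, axis=1) -> Tensor:
    """Stack equally shaped tensors along a new axis (time axis assembly)."""
    tensors = list(tensors)
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def bwd(g):
        for i, t in enumerate(tensors):
            t._accumulate(np.take(g, i, axis=axis))

    out.backward_fn = bwd
    return out


def flip(a: Tensor, axis: int) -> Tensor:
    out = Tensor(np.flip(a.data, axis=axis), parents=(a,))
    out.backward_fn = lambda g: a._accumulate(np.flip(g, axis=axis))
    return out


def mean(a: Tensor) -> Tensor:
    out = Tensor(a.data.mean(), parents=(a,))
    out.backward_fn = lambda g: a._accumulate(np.full(a.shape, g / a.data.size))
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid 1-D convolution: x (B,T,C), w (k,C,F), b (F) -> (B,T-k+1,F)."""
    k = w.shape[0]
    T = x.shape[1]
    y = np.zeros((x.shape[0], T - k + 1, w.shape[2]))
    for dk in range(k):
        y += x.data[:, dk:T - k + 1 + dk, :] @ w.data[dk]
    y += b.data
    out = Tensor(y, parents=(x, w, b))

    def bwd(g):
        gx = np.zeros_like(x.data)
        gw = np.zeros_like(w.data)
        for dk in range(k):
            xs = x.data[:, dk:T - k + 1 + dk, :]
            gw[dk] = np.einsum("btc,btf->cf", xs, g)
            gx[:, dk:T - k + 1 + dk, :] += g @ w.data[dk].T
        x._accumulate(gx)
        w._accumulate(gw)
        b._accumulate(g.sum(axis=(0, 1)))

    out.backward_fn = bwd
    return out


def max_pool1d(x: Tensor, pool: int = 2) -> Tensor:
    """Non-overlapping temporal max pooling; trailing remainder truncated."""
    B, T, C = x.shape
    To = T // pool
    xt = x.data[:, :To * pool, :].reshape(B, To, pool, C)
    arg = xt.argmax(axis=2)
    out = Tensor(xt.max(axis=2), parents=(x,))

    def bwd(g):
        gx = np.zeros_like(x.data)
        gblock = np.zeros((B, To, pool, C))
        np.put_along_axis(gblock, arg[:, :, None, :], g[:, :, None, :], axis=2)
        gx[:, :To * pool, :] = gblock.reshape(B, To * pool, C)
        x._accumulate(gx)

    out.backward_fn = bwd
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, y_onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy of softmax(logits) against one-hot y."""
    p = softmax(logits.data)
    n = logits.shape[0]
    loss = -np.sum(y_onehot * np.log(np.clip(p, 1e-12, None))) / n
    out = Tensor(loss, parents=(logits,))
    out.backward_fn = lambda g: logits._accumulate(g * (p - y_onehot) / n)
    return out
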