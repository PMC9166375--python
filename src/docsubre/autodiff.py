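"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the path encoder and the shared-weight CNN
need: broadcasting arithmetic, last-axis matrix multiplication against 2-D
weight matrices, elementwise nonlinearities, concatenation, row gathering
from lookup tables, axis slicing, masked maxima with tie-splitting
gradients, and a fused weighted softmax cross-entropy.  Everything runs in
float64; gradient correctness is enforced by finite-difference tests.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add",
    "mul",
    "matmul",
    "tanh",
    "sigmoid",
    "relu",
    "concat",
    "expand",
    "reshape",
    "take_rows",
    "slice_axis",
    "masked_max",
    "reduce_sum",
    "sum_squares",
    "weighted_softmax_cross_entropy",
    "softmax",
    "glorot_uniform",
    "Adam",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Collapse a broadcasted gradient back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, parents=(), backward=None, name=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def constant(data) -> Tensor:
    return Tensor(data, requires_grad=False)


def parameter(data, name=None) -> Tensor:
    return Tensor(data, requires_grad=True, name=name)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


def _node(data, parents, backward) -> Tensor:
    # Graph edges are only kept where a gradient can flow.
    needs = any(p.requires_grad or p._parents for p in parents)
    if not needs:
        return constant(data)
    out = Tensor(data, requires_grad=True, parents=parents, backward=backward)
    return out


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_sum_to_shape(g, a.data.shape))
        b._accumulate(_sum_to_shape(g, b.data.shape))

    return _node(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_sum_to_shape(g * b.data, a.data.shape))
        b._accumulate(_sum_to_shape(g * a.data, b.data.shape))

    return _node(data, (a, b), backward)


def matmul(x, w) -> Tensor:
    """``x @ w`` where x is [..., m] and w is a 2-D [m, n] matrix."""
    x, w = _as_tensor(x), _as_tensor(w)
    if w.data.ndim != 2:
        raise ValueError("matmul expects a 2-D weight matrix")
    data = x.data @ w.data

    def backward(g):
        x._accumulate(g @ w.data.T)
        xr = x.data.reshape(-1, x.data.shape[-1])
        gr = g.reshape(-1, g.shape[-1])
        w._accumulate(xr.T @ gr)

    return _node(data, (x, w), backward)


def tanh(x) -> Tensor:
    x = _as_tensor(x)
    data = np.tanh(x.data)

    def backward(g):
        x._accumulate(g * (1.0 - data * data))

    return _node(data, (x,), backward)


def sigmoid(x) -> Tensor:
    x = _as_tensor(x)
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        x._accumulate(g * data * (1.0 - data))

    return _node(data, (x,), backward)


def relu(x) -> Tensor:
    x = _as_tensor(x)
    data = np.maximum(x.data, 0.0)

    def backward(g):
        x._accumulate(g * (x.data > 0.0))

    return _node(data, (x,), backward)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis if axis >= 0 else g.ndim + axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _node(data, tuple(tensors), backward)


def take_rows(table, idx) -> Tensor:
    """Gather rows ``table[idx]``; idx is an integer array of any shape."""
    table = _as_tensor(table)
    idx = np.asarray(idx, dtype=np.intp)
    data = table.data[idx]

    def backward(g):
        acc = np.zeros_like(table.data)
        np.add.at(acc, idx.reshape(-1), g.reshape(-1, g.shape[-1]))
        table._accumulate(acc)

    return _node(data, (table,), backward)


def reshape(x, shape) -> Tensor:
    x = _as_tensor(x)
    data = x.data.reshape(shape)

    def backward(g):
        x._accumulate(g.reshape(x.data.shape))

    return _node(data, (x,), backward)


def expand(x, axis, size) -> Tensor:
    """Insert an axis of length ``size`` (repeat); backward sums over it."""
    x = _as_tensor(x)
    data = np.repeat(np.expand_dims(x.data, axis), size, axis=axis)

    def backward(g):
        x._accumulate(g.sum(axis=axis))

    return _node(data, (x,), backward)


def slice_axis(x, axis, start, stop) -> Tensor:
    x = _as_tensor(x)
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, stop)
    sl = tuple(sl)
    data = x.data[sl]

    def backward(g):
        acc = np.zeros_like(x.data)
        acc[sl] = g
        x._accumulate(acc)

    return _node(data, (x,), backward)


_NEG_INF = -1e30


def masked_max(x, mask, axes, neutral=0.0) -> Tensor:
    """Maximum of ``x`` over ``axes`` restricted to ``mask``.

    Positions with mask == 0 never win; groups whose mask is empty yield
    ``neutral`` and receive no gradient.  Gradient at a group is split
    equally among tied maxima (keeps finite-difference checks honest).
    """
    x = _as_tensor(x)
    mask = np.asarray(mask, dtype=bool)
    mask_b = np.broadcast_to(mask, x.data.shape)
    axes = tuple(ax % x.data.ndim for ax in axes)
    filled = np.where(mask_b, x.data, _NEG_INF)
    mx = filled.max(axis=axes, keepdims=True)
    valid = mask_b.any(axis=axes, keepdims=True)
    data_keep = np.where(valid, mx, neutral)
    data = np.squeeze(data_keep, axis=axes)

    def backward(g):
        g_keep = np.expand_dims(g, axes) if axes else g
        winners = (filled == mx) & mask_b & valid
        counts = winners.sum(axis=axes, keepdims=True)
        counts = np.where(counts == 0, 1, counts)
        x._accumulate(np.where(winners, g_keep / counts, 0.0))

    return _node(data, (x,), backward)


def reduce_sum(x, axes=None) -> Tensor:
    x = _as_tensor(x)
    if axes is None:
        data = x.data.sum()

        def backward(g):
            x._accumulate(np.full_like(x.data, float(g)))

    else:
        axes = tuple(ax % x.data.ndim for ax in axes)
        data = x.data.sum(axis=axes)

        def backward(g):
            x._accumulate(np.broadcast_to(np.expand_dims(g, axes), x.data.shape).copy())

    return _node(data, (x,), backward)


def sum_squares(tensors) -> Tensor:
    """sum of ||t||^2 over a list of tensors (L2 penalty term)."""
    tensors = [_as_tensor(t) for t in tensors]
    data = float(sum(np.sum(t.data * t.data) for t in tensors))

    def backward(g):
        for t in tensors:
            t._accumulate(2.0 * float(g) * t.data)

    return _node(np.asarray(data), tuple(tensors), backward)


def softmax(logits: np.ndarray, axis=-1) -> np.ndarray:
    """Plain numpy softmax (used outside the graph for prediction)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)


def weighted_softmax_cross_entropy(logits, labels, weights, floor=1e-12) -> Tensor:
    """Mean of per-example class-weighted cross-entropy.

    logits: [B, C] tensor; labels: [B] int array; weights: [B] float array
    (the class weight of each example's gold label).
    """
    logits = _as_tensor(logits)
    labels = np.asarray(labels, dtype=np.intp)
    weights = np.asarray(weights, dtype=np.float64)
    probs = softmax(logits.data, axis=-1)
    b = probs.shape[0]
    gold = np.clip(probs[np.arange(b), labels], floor, None)
    data = np.asarray((weights * -np.log(gold)).mean())

    def backward(g):
        grad = probs.copy()
        grad[np.arange(b), labels] -= 1.0
        grad *= (weights / b)[:, None] * float(g)
        logits._accumulate(grad)

    return _node(data, (logits,), backward)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with an optional per-row max-norm constraint on 2-D weights."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8, max_norm=None):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.max_norm = max_norm
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
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
            if self.max_norm is not None and p.data.ndim == 2:
                norms = np.linalg.norm(p.data, axis=1, keepdims=True)
                scale = np.minimum(1.0, self.max_norm / np.maximum(norms, 1e-12))
                p.data *= scale

    def zero_grad(self):
        for p in self.params:
            p.grad = None
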