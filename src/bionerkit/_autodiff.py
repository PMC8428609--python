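"""Minimal reverse-mode automatic differentiation over numpy arrays.

Internal infrastructure for the recurrent models.  Supports exactly the
operations the character LM and the BiLSTM tagger need: affine maps,
pointwise nonlinearities, concatenation/slicing and softmax cross-entropy.
All arrays are float64 so numerical tests can use tight tolerances.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "cross_entropy", "clip_gradients", "sgd_step"]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction -------------------------------------------------

    def _make(self, data, parents, backward):
        return Tensor(data, parents=parents, backward=backward)

    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def backward(grad, a=self, b=other):
            _accum(a, _unbroadcast(grad, a.data.shape))
            _accum(b, _unbroadcast(grad, b.data.shape))

        return self._make(out_data, (self, other), backward)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def backward(grad, a=self, b=other):
            _accum(a, _unbroadcast(grad * b.data, a.data.shape))
            _accum(b, _unbroadcast(grad * a.data, b.data.shape))

        return self._make(out_data, (self, other), backward)

    def __sub__(self, other):
        return self + (_as_tensor(other) * Tensor(-1.0))

    def matmul(self, other):
        other = _as_tensor(other)
        out_data = self.data @ other.data

        def backward(grad, a=self, b=other):
            _accum(a, grad @ b.data.T)
            _accum(b, a.data.T @ grad)

        return self._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(grad, a=self, y=out_data):
            _accum(a, grad * y * (1.0 - y))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(grad, a=self, y=out_data):
            _accum(a, grad * (1.0 - y * y))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, key):
        out_data = self.data[key]

        def backward(grad, a=self, key=key):
            full = np.zeros_like(a.data)
            np.add.at(full, key, grad)
            _accum(a, full)

        return self._make(out_data, (self,), backward)

    def sum(self):
        out_data = np.asarray(self.data.sum())

        def backward(grad, a=self):
            _accum(a, np.broadcast_to(grad, a.data.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self):
        n = self.data.size
        return self.sum() * Tensor(1.0 / n)

    @staticmethod
    def concat(tensors, axis=-1):
        tensors = [_as_tensor(t) for t in tensors]
        out_data = np.concatenate([t.data for t in tensors], axis=axis)
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(grad, parts=tensors, offsets=offsets, axis=axis):
            for t, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                _accum(t, grad[tuple(idx)])

        return Tensor(out_data, parents=tuple(tensors), backward=backward)

    @staticmethod
    def stack_rows(tensors):
        """Stack 1-D tensors into a matrix (n, d)."""
        tensors = [_as_tensor(t) for t in tensors]
        out_data = np.stack([t.data for t in tensors], axis=0)

        def backward(grad, parts=tensors):
            for i, t in enumerate(parts):
                _accum(t, grad[i])

        return Tensor(out_data, parents=tuple(tensors), backward=backward)

    # ---- backward pass ------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs can exceed the recursion limit
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(tensor, grad):
    if not tensor.requires_grad:
        return
    if tensor.grad is None:
        tensor.grad = np.array(grad, dtype=np.float64)
    else:
        tensor.grad += grad


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy (natural log) of row-wise logits.

    Fused op: the softmax Jacobian is applied analytically in the backward
    pass, keeping the graph small for long character sequences.
    """
    targets = np.asarray(targets, dtype=np.intp)
    z = logits.data
    zmax = z.max(axis=-1, keepdims=True)
    exp = np.exp(z - zmax)
    probs = exp / exp.sum(axis=-1, keepdims=True)
    n = targets.shape[0]
    picked = probs[np.arange(n), targets]
    loss = -np.log(np.maximum(picked, 1e-300)).mean()

    def backward(grad, a=logits, probs=probs, targets=targets, n=n):
        g = probs.copy()
        g[np.arange(n), targets] -= 1.0
        _accum(a, (grad / n) * g)

    return Tensor(np.asarray(loss), parents=(logits,), backward=backward)


def clip_gradients(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = total ** 0.5
    if norm > max_norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return norm


def sgd_step(params, lr: float):
    for p in params:
        if p.grad is not None:
            p.data -= lr * p.grad


def zero_gradients(params):
    for p in params:
        p.grad = None
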