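"""A small reverse-mode automatic differentiation engine on NumPy arrays.

Provides exactly the operations the package's recurrent models need:
matrix products, broadcast add/multiply, the LSTM gate nonlinearities,
column slicing/concatenation, embedding lookup, elementwise maximum (for
masked max-pooling) and fused softmax cross-entropy / mean-squared-error
losses. Gradients are accumulated by topological traversal from the loss.

Float32 throughout; every stochastic choice (initialization, dropout masks)
lives outside this module and is seeded by the caller.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the graph."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if id(parent) not in visited:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _result(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accumulate(t: Tensor, grad: np.ndarray) -> None:
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = grad.copy()
    else:
        t.grad += grad


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _result(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _result(a.data * b.data, (a, b), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(g):
        _accumulate(a, g * s)

    return _result(a.data * s, (a,), backward)


def mul_const(a: Tensor, mask: np.ndarray) -> Tensor:
    """Elementwise product with a constant array (dropout masks)."""

    def backward(g):
        _accumulate(a, _unbroadcast(g * mask, a.data.shape))

    return _result(a.data * mask, (a,), backward)


def add_const(a: Tensor, c: np.ndarray) -> Tensor:
    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))

    return _result(a.data + c, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _result(a.data @ b.data, (a, b), backward)


def matmul_nt(a: Tensor, b: Tensor) -> Tensor:
    """``a @ b.T`` — used for weight-tied decoders."""

    def backward(g):
        _accumulate(a, g @ b.data)
        _accumulate(b, g.T @ a.data)

    return _result(a.data @ b.data.T, (a, b), backward)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return _result(out_data, (a,), backward)


def tanh(a: Tensor) -> Tensor:
    out_data = np.tanh(a.data)

    def backward(g):
        _accumulate(a, g * (1.0 - out_data * out_data))

    return _result(out_data, (a,), backward)


def relu(a: Tensor) -> Tensor:
    out_data = np.maximum(a.data, 0.0)

    def backward(g):
        _accumulate(a, g * (a.data > 0))

    return _result(out_data, (a,), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise max; gradient routed to the winner (ties split evenly)."""
    a_wins = a.data > b.data
    ties = a.data == b.data

    def backward(g):
        _accumulate(a, g * (a_wins + 0.5 * ties))
        _accumulate(b, g * (~a_wins & ~ties) + g * 0.5 * ties)

    return _result(np.maximum(a.data, b.data), (a, b), backward)


def slice_cols(a: Tensor, start: int, stop: int) -> Tensor:
    def backward(g):
        if a.requires_grad or a._parents:
            full = np.zeros_like(a.data)
            full[:, start:stop] = g
            _accumulate(a, full)

    return _result(a.data[:, start:stop], (a,), backward)


def concat_cols(tensors: list[Tensor]) -> Tensor:
    widths = [t.data.shape[1] for t in tensors]

    def backward(g):
        offset = 0
        for t, w in zip(tensors, widths):
            _accumulate(t, g[:, offset : offset + w])
            offset += w

    return _result(np.concatenate([t.data for t in tensors], axis=1), tuple(tensors), backward)


def concat_rows(tensors: list[Tensor]) -> Tensor:
    heights = [t.data.shape[0] for t in tensors]

    def backward(g):
        offset = 0
        for t, h in zip(tensors, heights):
            _accumulate(t, g[offset : offset + h])
            offset += h

    return _result(np.concatenate([t.data for t in tensors], axis=0), tuple(tensors), backward)


def embedding(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add backward."""
    idx = np.asarray(indices, dtype=np.int64)

    def backward(g):
        if weight.requires_grad or weight._parents:
            full = np.zeros_like(weight.data)
            np.add.at(full, idx, g)
            _accumulate(weight, full)

    return _result(weight.data[idx], (weight,), backward)


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of rows of ``logits`` against integer ``targets``."""
    t = np.asarray(targets, dtype=np.int64)
    n = logits.data.shape[0]
    shifted = logits.data - logits.data.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    probs = exp / exp.sum(axis=1, keepdims=True)
    loss = -np.mean(np.log(probs[np.arange(n), t] + 1e-12))

    def backward(g):
        grad = probs.copy()
        grad[np.arange(n), t] -= 1.0
        _accumulate(logits, g * grad / n)

    return _result(loss, (logits,), backward)


def mse_loss(pred: Tensor, targets: np.ndarray) -> Tensor:
    """Mean squared error of ``pred`` (any shape) against constant targets."""
    t = np.asarray(targets, dtype=np.float32).reshape(pred.data.shape)
    diff = pred.data - t
    loss = np.mean(diff * diff)

    def backward(g):
        _accumulate(pred, g * 2.0 * diff / diff.size)

    return _result(loss, (pred,), backward)


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Plain (non-differentiable) softmax over the last axis."""
    shifted = logits - logits.max(axis=-1, keepdims=True)
    exp = np.exp(shifted)
    return exp / exp.sum(axis=-1, keepdims=True)
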