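"""Minimal reverse-mode automatic differentiation over numpy arrays.

The training path of the gene-set binary network needs gradients through a
fixed, moderately sized computation graph: binarization with a
straight-through estimator, rank trimming against a learnable cutoff,
enrichment-score algebra, batch standardization and a softmax
cross-entropy.  This module provides exactly the operations that graph
uses, with a classic tape: every :class:`Tensor` remembers its parents and
a closure mapping the output gradient to parent gradients.  Gradients are
accumulated by reverse topological traversal.

Only float64 dense arrays are supported (plus a left sparse matmul with a
constant scipy matrix).  Broadcasting follows numpy rules; gradients are
summed back to the parent's shape.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as _sparse


class Tensor:
    """Node in the computation graph.

    Parameters
    ----------
    value
        The numpy value of this node.
    parents
        Tuple of parent ``Tensor`` objects.
    grad_fn
        Callable mapping the gradient at this node to a tuple of gradients,
        one per parent (``None`` entries are skipped).  Leaves have no
        ``grad_fn``.
    """

    __slots__ = ("value", "parents", "grad_fn", "grad")

    def __init__(self, value, parents=(), grad_fn=None):
        self.value = np.asarray(value, dtype=float)
        self.parents = tuple(parents)
        self.grad_fn = grad_fn
        self.grad = None

    @property
    def shape(self):
        return self.value.shape

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self):
        """Accumulate gradients of ``self`` (a scalar) into the graph."""
        if self.value.size != 1:
            raise ValueError("backward() requires a scalar root")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            if node.grad_fn is None:
                continue
            grads = node.grad_fn(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is not None:
                    parent.grad = parent.grad + g


def wrap(x) -> Tensor:
    """Return ``x`` as a constant leaf Tensor if it is not one already."""
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    grad = np.asarray(grad, dtype=float)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = wrap(a), wrap(b)
    return Tensor(
        a.value + b.value,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b) -> Tensor:
    a, b = wrap(a), wrap(b)
    return Tensor(
        a.value - b.value,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def mul(a, b) -> Tensor:
    a, b = wrap(a), wrap(b)
    return Tensor(
        a.value * b.value,
        (a, b),
        lambda g: (
            _unbroadcast(g * b.value, a.shape),
            _unbroadcast(g * a.value, b.shape),
        ),
    )


def div(a, b) -> Tensor:
    a, b = wrap(a), wrap(b)
    return Tensor(
        a.value / b.value,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.value, a.shape),
            _unbroadcast(-g * a.value / b.value**2, b.shape),
        ),
    )


def square(a) -> Tensor:
    a = wrap(a)
    return Tensor(a.value**2, (a,), lambda g: (2.0 * a.value * g,))


def sqrt(a) -> Tensor:
    a = wrap(a)
    out = np.sqrt(a.value)
    return Tensor(out, (a,), lambda g: (g * 0.5 / np.maximum(out, 1e-300),))


def maximum(a, b) -> Tensor:
    """Elementwise maximum; on ties the gradient flows to ``a``."""
    a, b = wrap(a), wrap(b)
    mask = a.value >= b.value
    return Tensor(
        np.maximum(a.value, b.value),
        (a, b),
        lambda g: (
            _unbroadcast(g * mask, a.shape),
            _unbroadcast(g * ~mask, b.shape),
        ),
    )


def minimum(a, b) -> Tensor:
    """Elementwise minimum; on ties the gradient flows to ``a``."""
    a, b = wrap(a), wrap(b)
    mask = a.value <= b.value
    return Tensor(
        np.minimum(a.value, b.value),
        (a, b),
        lambda g: (
            _unbroadcast(g * mask, a.shape),
            _unbroadcast(g * ~mask, b.shape),
        ),
    )


def relu(a) -> Tensor:
    a = wrap(a)
    mask = a.value > 0
    return Tensor(a.value * mask, (a,), lambda g: (g * mask,))


# ---------------------------------------------------------------------------
# reductions and reshaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = wrap(a)
    out = a.value.sum(axis=axis, keepdims=keepdims)

    def grad_fn(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.shape).copy(),)

    return Tensor(out, (a,), grad_fn)


def tmax(a, axis=None) -> Tensor:
    """Max reduction; subgradient routed to the first attaining entry."""
    a = wrap(a)
    out = a.value.max(axis=axis)

    def grad_fn(g):
        grad = np.zeros_like(a.value)
        if axis is None:
            idx = np.unravel_index(np.argmax(a.value), a.shape)
            grad[idx] = g
        else:
            idx = np.argmax(a.value, axis=axis)
            grad_idx = list(np.indices(out.shape))
            grad_idx.insert(axis, idx)
            grad[tuple(grad_idx)] = g
        return (grad,)

    return Tensor(out, (a,), grad_fn)


def reshape(a, shape) -> Tensor:
    a = wrap(a)
    return Tensor(
        a.value.reshape(shape), (a,), lambda g: (np.asarray(g).reshape(a.shape),)
    )


def concat(tensors, axis=0) -> Tensor:
    tensors = [wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def grad_fn(g):
        return tuple(np.split(np.asarray(g), splits, axis=axis))

    return Tensor(np.concatenate([t.value for t in tensors], axis=axis), tensors, grad_fn)


# ---------------------------------------------------------------------------
# linear algebra
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    """Matrix product supporting (2D @ 2D) and (2D @ 1D)."""
    a, b = wrap(a), wrap(b)
    out = a.value @ b.value
    if b.value.ndim == 1:
        def grad_fn(g):
            g = np.asarray(g)
            return (np.outer(g, b.value), a.value.T @ g)
    else:
        def grad_fn(g):
            g = np.asarray(g)
            return (g @ b.value.T, a.value.T @ g)
    return Tensor(out, (a, b), grad_fn)


def sparse_matmul(mat, b) -> Tensor:
    """``mat @ b`` where ``mat`` is a constant scipy sparse matrix."""
    if not _sparse.issparse(mat):
        raise TypeError("sparse_matmul expects a scipy sparse matrix")
    b = wrap(b)
    mat_t = mat.T.tocsr()
    return Tensor(
        np.asarray(mat @ b.value), (b,), lambda g: (np.asarray(mat_t @ g),)
    )


# ---------------------------------------------------------------------------
# straight-through estimators
# ---------------------------------------------------------------------------

def binarize_ste(w, threshold=0.0, clip=1.0) -> Tensor:
    """Binarize ``w`` at ``threshold`` (strict >) with an STE backward.

    Forward: 1 where ``w > threshold``, else 0.  Backward: the gradient
    passes through unchanged where ``|w| <= clip`` and is zeroed outside —
    the derivative of the hardtanh surrogate.
    """
    w = wrap(w)
    mask = np.abs(w.value) <= clip
    return Tensor((w.value > threshold).astype(float), (w,), lambda g: (g * mask,))


def round_ste(a) -> Tensor:
    """Round to nearest integer; identity gradient (straight-through)."""
    a = wrap(a)
    return Tensor(np.round(a.value), (a,), lambda g: (np.asarray(g),))


# ---------------------------------------------------------------------------
# loss heads
# ---------------------------------------------------------------------------

def weighted_cross_entropy(logits, targets, weights) -> Tensor:
    """Weighted sum of per-row softmax cross-entropies.

    ``logits`` is a (C, G) Tensor, ``targets`` an int array of 0-based
    class indices, ``weights`` a non-negative array of per-row weights.
    Returns ``sum_w weights_w * CE_w`` computed with the log-sum-exp trick.
    """
    logits = wrap(logits)
    targets = np.asarray(targets, dtype=int)
    weights = np.asarray(weights, dtype=float)
    z = logits.value
    zmax = z.max(axis=1, keepdims=True)
    lse = zmax[:, 0] + np.log(np.exp(z - zmax).sum(axis=1))
    ce = lse - z[np.arange(z.shape[0]), targets]
    softmax = np.exp(z - zmax)
    softmax /= softmax.sum(axis=1, keepdims=True)

    def grad_fn(g):
        onehot = np.zeros_like(z)
        onehot[np.arange(z.shape[0]), targets] = 1.0
        return (float(g) * weights[:, None] * (softmax - onehot),)

    return Tensor(float(np.dot(weights, ce)), (logits,), grad_fn)
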