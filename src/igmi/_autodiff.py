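"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The model in this package is small (a few dozen tensor operations per forward
pass over batches of fixed-size residue subgraphs), so a compact tape-based
autodiff layer over NumPy is sufficient: per-operation Python overhead is
negligible next to the underlying BLAS calls.

Only the primitives the model needs are provided: broadcast arithmetic,
batched ``matmul``, elementwise nonlinearities, reductions, shape ops,
gather (embedding lookup), a masked softmax, and dropout.  Gradients follow
the standard vector-Jacobian rules; broadcasting is undone by summing over
the broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "matmul",
    "relu",
    "sigmoid",
    "softplus",
    "exp",
    "sqrt",
    "take",
    "masked_softmax",
    "layer_norm",
    "dropout",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional entry on the gradient tape.

    ``backward()`` on a scalar result accumulates ``.grad`` on every leaf
    tensor created with ``requires_grad=True``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # keep ndarray ops from hijacking Tensor ops

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], Sequence[np.ndarray | None]] | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise ValueError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar output")
            grad = np.ones_like(self.data)
        _run_backward(self, np.asarray(grad, dtype=self.data.dtype))


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, Iterable[Tensor]]] = [(root, iter(root._parents))]
    seen.add(id(root))
    while stack:
        cur, it = stack[-1]
        advanced = False
        for p in it:
            if id(p) not in seen:
                seen.add(id(p))
                stack.append((p, iter(p._parents)))
                advanced = True
                break
        if not advanced:
            order.append(cur)
            stack.pop()
    return order


def _run_backward(root: Tensor, grad: np.ndarray) -> None:
    grads: dict[int, np.ndarray] = {id(root): grad}
    for node in reversed(_toposort(root)):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node._backward is None:
            node.grad = g if node.grad is None else node.grad + g
            continue
        for parent, pg in zip(node._parents, node._backward(g)):
            if pg is None or not parent.requires_grad:
                continue
            key = id(parent)
            grads[key] = grads[key] + pg if key in grads else pg


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _op(data: np.ndarray, parents: Sequence[Tensor],
        backward: Callable[[np.ndarray], Sequence[np.ndarray | None]]) -> Tensor:
    out = Tensor.__new__(Tensor)
    out.data = data
    out.grad = None
    out.requires_grad = any(p.requires_grad for p in parents)
    out._parents = tuple(parents) if out.requires_grad else ()
    out._backward = backward if out.requires_grad else None
    return out


# -- arithmetic -----------------------------------------------------------

def _add(a: Tensor, b: Tensor) -> Tensor:
    return _op(a.data + b.data, (a, b),
               lambda g: (_unbroadcast(g, a.data.shape),
                          _unbroadcast(g, b.data.shape)))


def _sub(a: Tensor, b: Tensor) -> Tensor:
    return _op(a.data - b.data, (a, b),
               lambda g: (_unbroadcast(g, a.data.shape),
                          _unbroadcast(-g, b.data.shape)))


def _mul(a: Tensor, b: Tensor) -> Tensor:
    return _op(a.data * b.data, (a, b),
               lambda g: (_unbroadcast(g * b.data, a.data.shape)
                          if a.requires_grad else None,
                          _unbroadcast(g * a.data, b.data.shape)
                          if b.requires_grad else None))


def _div(a: Tensor, b: Tensor) -> Tensor:
    return _op(a.data / b.data, (a, b),
               lambda g: (_unbroadcast(g / b.data, a.data.shape)
                          if a.requires_grad else None,
                          _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape)
                          if b.requires_grad else None))


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    # fast path: x @ W with a plain weight matrix — collapse the leading
    # axes into one 2-D GEMM instead of NumPy's batched loop
    if b.data.ndim == 2 and a.data.ndim > 2:
        lead = a.data.shape[:-1]
        a2 = np.ascontiguousarray(a.data).reshape(-1, a.data.shape[-1])
        out = (a2 @ b.data).reshape(lead + (b.data.shape[-1],))

        def backward2d(g: np.ndarray):
            g2 = g.reshape(-1, g.shape[-1])
            ga = ((g2 @ b.data.T).reshape(a.data.shape)
                  if a.requires_grad else None)
            gb = a2.T @ g2 if b.requires_grad else None
            return ga, gb

        return _op(out, (a, b), backward2d)

    def backward(g: np.ndarray):
        ga = (_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
              if a.requires_grad else None)
        gb = (_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)
              if b.requires_grad else None)
        return ga, gb

    return _op(a.data @ b.data, (a, b), backward)


def _coerce(other, ref: Tensor) -> Tensor:
    """Wrap operands; python scalars adopt the tensor's dtype (no upcast)."""
    if isinstance(other, (int, float)):
        return Tensor(np.asarray(other, dtype=ref.data.dtype))
    return as_tensor(other)


Tensor.__add__ = lambda self, other: _add(self, _coerce(other, self))
Tensor.__radd__ = lambda self, other: _add(_coerce(other, self), self)
Tensor.__sub__ = lambda self, other: _sub(self, _coerce(other, self))
Tensor.__rsub__ = lambda self, other: _sub(_coerce(other, self), self)
Tensor.__mul__ = lambda self, other: _mul(self, _coerce(other, self))
Tensor.__rmul__ = lambda self, other: _mul(_coerce(other, self), self)
Tensor.__truediv__ = lambda self, other: _div(self, _coerce(other, self))
Tensor.__rtruediv__ = lambda self, other: _div(_coerce(other, self), self)
Tensor.__neg__ = lambda self: _mul(self, Tensor(np.asarray(-1.0, dtype=self.data.dtype)))
Tensor.__matmul__ = matmul
Tensor.__rmatmul__ = lambda self, other: matmul(as_tensor(other), self)


# -- elementwise nonlinearities -------------------------------------------

def relu(x) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    return _op(x.data * mask, (x,), lambda g: (g * mask,))


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    y = y.astype(x.data.dtype)
    return _op(y, (x,), lambda g: (g * y * (1.0 - y),))


def softplus(x) -> Tensor:
    """Numerically stable log(1 + exp(x))."""
    x = as_tensor(x)
    d = x.data
    y = np.where(d > 30, d, np.log1p(np.exp(np.minimum(d, 30)))).astype(d.dtype)
    s = (1.0 / (1.0 + np.exp(-np.clip(d, -60, 60)))).astype(d.dtype)
    return _op(y, (x,), lambda g: (g * s,))


def exp(x) -> Tensor:
    x = as_tensor(x)
    y = np.exp(x.data)
    return _op(y, (x,), lambda g: (g * y,))


def sqrt(x) -> Tensor:
    x = as_tensor(x)
    y = np.sqrt(x.data)
    return _op(y, (x,), lambda g: (g * 0.5 / np.maximum(y, np.finfo(y.dtype).tiny),))


# -- reductions and shape ops ---------------------------------------------

def _sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g: np.ndarray):
        if axis is None:
            return (np.broadcast_to(g, x.data.shape).copy(),)
        gg = g
        if not keepdims:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            axes = tuple(a % x.data.ndim for a in axes)
            for a in sorted(axes):
                gg = np.expand_dims(gg, a)
        return (np.broadcast_to(gg, x.data.shape).copy(),)

    return _op(data, (x,), backward)


def _mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return _sum(x, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    return _op(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def _moveaxis(x: Tensor, src, dst) -> Tensor:
    # contiguous output: downstream ufuncs on strided views are many times
    # slower than the one extra copy
    return _op(np.ascontiguousarray(np.moveaxis(x.data, src, dst)), (x,),
               lambda g: (np.ascontiguousarray(np.moveaxis(g, dst, src)),))


def _getitem(x: Tensor, key) -> Tensor:
    data = x.data[key]

    def backward(g: np.ndarray):
        gx = np.zeros_like(x.data)
        np.add.at(gx, key, g)
        return (gx,)

    return _op(data, (x,), backward)


Tensor.sum = _sum
Tensor.mean = _mean
Tensor.reshape = _reshape
Tensor.moveaxis = _moveaxis
Tensor.__getitem__ = _getitem


def take(weights, idx: np.ndarray) -> Tensor:
    """Embedding lookup ``weights[idx]`` with scatter-add backward.

    The backward pass accumulates per-row gradients with ``np.bincount``
    (one call per embedding column), which is far faster than ``np.add.at``
    for the large index arrays produced by pairwise features.
    """
    weights = as_tensor(weights)
    idx = np.asarray(idx)
    data = weights.data[idx]
    flat_idx = idx.reshape(-1)
    V, E = weights.data.shape

    def backward(g: np.ndarray):
        gf = g.reshape(-1, E)
        gw = np.empty_like(weights.data)
        for e in range(E):
            gw[:, e] = np.bincount(flat_idx, weights=gf[:, e], minlength=V)
        return (gw,)

    return _op(data, (weights,), backward)


def concat(tensors: Iterable, axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    splits = np.cumsum([t.data.shape[axis] for t in ts])[:-1]
    return _op(data, ts, lambda g: tuple(np.split(g, splits, axis=axis)))


def stack(tensors: Iterable, axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in ts], axis=axis)
    return _op(data, ts,
               lambda g: tuple(np.moveaxis(g, axis, 0)[i] for i in range(len(ts))))


def masked_softmax(logits, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to positions where ``mask`` is True.

    Masked positions receive weight 0.  A row with no valid position at all
    falls back to the uniform distribution over the full axis (such rows only
    arise for padding queries and are masked out downstream); no gradient
    flows through fallback rows.
    """
    logits = as_tensor(logits)
    mask = np.asarray(mask, dtype=bool)
    # additive -inf on masked keys (exp underflows to exactly 0 there)
    add = np.where(mask, 0.0, -np.inf).astype(logits.data.dtype)
    x = logits.data + add
    rowmax = np.max(x, axis=axis, keepdims=True)
    rowmax = np.where(np.isfinite(rowmax), rowmax, 0.0)
    e = np.exp(x - rowmax)
    s = e.sum(axis=axis, keepdims=True)
    n = logits.data.shape[axis]
    y = np.where(s > 0, e / np.where(s > 0, s, 1.0), 1.0 / n).astype(logits.data.dtype)

    def backward(g: np.ndarray):
        inner = (g * y).sum(axis=axis, keepdims=True)
        gx = y * (g - inner)
        return (np.where(s > 0, gx, 0.0),)

    return _op(y, (logits,), backward)


def layer_norm(x, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis."""
    x = as_tensor(x)
    d = x.data
    mu = d.mean(axis=-1, keepdims=True)
    xc = d - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = xhat * gamma.data + beta.data

    def backward(g: np.ndarray):
        n = d.shape[-1]
        gx = None
        if x.requires_grad:
            gh = g * gamma.data
            gx = inv * (gh - gh.mean(axis=-1, keepdims=True)
                        - xhat * (gh * xhat).mean(axis=-1, keepdims=True))
        gg = ((g * xhat).reshape(-1, n).sum(axis=0)
              if gamma.requires_grad else None)
        gb = g.reshape(-1, n).sum(axis=0) if beta.requires_grad else None
        return gx, gg, gb

    return _op(out.astype(d.dtype), (x, gamma, beta), backward)


def dropout(x, p: float, rng: np.random.Generator, training: bool = True) -> Tensor:
    """Inverted dropout; identity when not training or ``p`` == 0."""
    x = as_tensor(x)
    if not training or p <= 0.0:
        return x
    keep = (rng.random(x.data.shape) >= p).astype(x.data.dtype) / (1.0 - p)
    return _op(x.data * keep, (x,), lambda g: (g * keep,))


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            step = self.lr * (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.eps)
            if self.weight_decay > 0:
                step = step + self.lr * self.weight_decay * p.data
            p.data = p.data - step
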