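"""Reverse-mode automatic differentiation over NumPy arrays.

A small, vectorized autodiff core providing exactly the operations the
sequence-classification network needs: elementwise arithmetic, matrix
multiplication, stride-1 1-D convolution, strided 1-D max-pooling, an
embedding lookup, reductions, and the usual nonlinearities.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward` via a
topological sweep, matching the semantics of mainstream frameworks so the
surrounding model code reads conventionally.

Design constraints:

* all convolutions in the network are stride 1, so :func:`conv1d` does not
  implement strides; downsampling happens only in :func:`maxpool1d`;
* max-pool padding uses ``-inf`` so padded positions can never win the max;
* :func:`sqrt` defines its gradient as 0 at 0 (a subgradient choice) so the
  Euclidean distance in the contrastive loss is exact at coincident points
  without an epsilon shifting the forward value.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A NumPy array with an optional place in a backward graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to the reflected Tensor operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- operators -----------------------------------------------------
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

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        if p != 2:
            raise NotImplementedError("only squaring is supported")
        return mul(self, self)

    def __matmul__(self, other):
        return matmul(self, other)

    # -- autodiff ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Run reverse-mode accumulation from this tensor.

        ``grad`` defaults to 1 for scalars.  Gradients are *accumulated*
        (+=) into every reachable tensor's ``.grad``; call an optimizer's
        ``zero_grad`` (or clear manually) between backward passes.
        """
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        _accumulate(self, np.asarray(grad, dtype=self.data.dtype))

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True)
    else:
        t.grad += g


def _node(data: np.ndarray, parents: Sequence[Tensor], backward_fn) -> Tensor:
    """Create an op result, wiring it into the graph only when needed."""
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if not _GRAD_ENABLED or not any(p.requires_grad or p._parents for p in parents):
        return Tensor(data)
    # backward_fn takes the output gradient directly: no closure over the
    # output tensor, hence no reference cycle and graphs free promptly
    out = Tensor(data, requires_grad=True)
    out._parents = parents
    out._backward = backward_fn
    return out


def _wants_grad(t: Tensor) -> bool:
    return t.requires_grad or bool(t._parents)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` to invert NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise arithmetic --------------------------------------------


def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        if _wants_grad(a):
            _accumulate(a, _unbroadcast(g, a.data.shape))
        if _wants_grad(b):
            _accumulate(b, _unbroadcast(g, b.data.shape))

    return _node(out, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        if _wants_grad(a):
            _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        if _wants_grad(b):
            _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def backward(g):
        if _wants_grad(a):
            _accumulate(a, g @ b.data.T)
        if _wants_grad(b):
            _accumulate(b, a.data.T @ g)

    return _node(out, (a, b), backward)


# -- nonlinearities ----------------------------------------------------


def relu(x) -> Tensor:
    x = as_tensor(x)
    out = np.maximum(x.data, 0)

    def backward(g):
        if _wants_grad(x):
            _accumulate(x, g * (out > 0))

    return _node(out, (x,), backward)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        if _wants_grad(x):
            _accumulate(x, g * out * (1.0 - out))

    return _node(out, (x,), backward)


def softmax(x, axis: int) -> Tensor:
    x = as_tensor(x)
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if _wants_grad(x):
            dot = (g * out).sum(axis=axis, keepdims=True)
            _accumulate(x, (g - dot) * out)

    return _node(out, (x,), backward)


def log(x) -> Tensor:
    x = as_tensor(x)
    out = np.log(x.data)

    def backward(g):
        if _wants_grad(x):
            _accumulate(x, g / x.data)

    return _node(out, (x,), backward)


def sqrt(x) -> Tensor:
    x = as_tensor(x)
    out = np.sqrt(x.data)

    def backward(g):
        if _wants_grad(x):
            _accumulate(x, np.where(out > 0, g / np.maximum(2.0 * out, 1e-30), 0.0))

    return _node(out, (x,), backward)


def clip(x, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the un-clipped region."""
    x = as_tensor(x)
    out = np.clip(x.data, lo, hi)
    mask = (x.data > lo) & (x.data < hi)

    def backward(g):
        if _wants_grad(x):
            _accumulate(x, g * mask)

    return _node(out, (x,), backward)


# -- reductions / shaping ----------------------------------------------


def _sum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    out = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if _wants_grad(x):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            _accumulate(x, np.broadcast_to(g, x.data.shape))

    return _node(out, (x,), backward)


def mean(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else x.data.shape[axis]
    return mul(_sum(x, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    out = x.data.reshape(shape)

    def backward(g):
        if _wants_grad(x):
            _accumulate(x, g.reshape(x.data.shape))

    return _node(out, (x,), backward)


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            if _wants_grad(t):
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                _accumulate(t, g[tuple(idx)])

    return _node(out, tensors, backward)


def take_rows(x, indices: np.ndarray) -> Tensor:
    """Gather rows of a 2-D tensor; scatter-adds on the way back."""
    x = as_tensor(x)
    indices = np.asarray(indices)
    out = x.data[indices]

    def backward(g):
        if _wants_grad(x):
            dx = np.zeros_like(x.data)
            np.add.at(dx, indices, g)
            _accumulate(x, dx)

    return _node(out, (x,), backward)


# -- structured ops ----------------------------------------------------


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """Stride-1 1-D convolution (cross-correlation).

    ``x``: (batch, C_in, L); ``w``: (C_out, C_in, K); symmetric zero
    padding ``pad`` on the position axis.  Output (batch, C_out, L') with
    L' = L + 2*pad - K + 1.
    """
    x, w = as_tensor(x), as_tensor(w)
    xd, wd = x.data, w.data
    batch, c_in, _ = xd.shape
    c_out, _, k = wd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad))) if pad else xd
    l_out = xp.shape[2] - k + 1
    # im2col: one GEMM per conv keeps the arithmetic in BLAS
    patches = sliding_window_view(xp, k, axis=2)  # view (B, C_in, L', K)
    cols = np.ascontiguousarray(patches.transpose(0, 2, 1, 3)).reshape(
        batch * l_out, c_in * k)
    w2d = wd.reshape(c_out, c_in * k)
    out2d = cols @ w2d.T  # (B*L', C_out)
    if b is not None:
        out2d += b.data
    out = out2d.reshape(batch, l_out, c_out).transpose(0, 2, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 1)).reshape(batch * l_out, c_out)
        if _wants_grad(w):
            _accumulate(w, (g2d.T @ cols).reshape(c_out, c_in, k))
        if b is not None and _wants_grad(b):
            _accumulate(b, g2d.sum(axis=0))
        if _wants_grad(x):
            dcols = (g2d @ w2d).reshape(batch, l_out, c_in, k).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            for kk in range(k):  # col2im scatter (K is small)
                dxp[:, :, kk : kk + l_out] += dcols[:, :, :, kk]
            _accumulate(x, dxp[:, :, pad : dxp.shape[2] - pad] if pad else dxp)

    return _node(out, parents, backward)


def maxpool1d(x: Tensor, kernel: int = 3, stride: int = 1, pad: int = 0) -> Tensor:
    """1-D max pooling with ``-inf`` padding (padding never wins)."""
    x = as_tensor(x)
    xd = x.data
    batch, channels, length = xd.shape
    if pad:
        xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad)), constant_values=-np.inf)
    else:
        xp = xd
    l_out = (xp.shape[2] - kernel) // stride + 1

    def offset_slice(kk):
        return xp[:, :, kk : kk + (l_out - 1) * stride + 1 : stride]

    out = offset_slice(0).copy()
    for kk in range(1, kernel):
        np.maximum(out, offset_slice(kk), out=out)

    def backward(g):
        if not _wants_grad(x):
            return
        # recover first-maximum offsets (argmax tie convention)
        sel = np.full(out.shape, -1, dtype=np.int8)
        for kk in range(kernel):
            np.copyto(sel, kk, where=(sel < 0) & (offset_slice(kk) == out))
        pos = np.arange(l_out)[None, None, :] * stride + sel.astype(np.int64) - pad
        dx = np.zeros_like(xd)
        bidx = np.broadcast_to(np.arange(batch)[:, None, None], pos.shape)
        cidx = np.broadcast_to(np.arange(channels)[None, :, None], pos.shape)
        np.add.at(dx, (bidx, cidx, pos), g)
        _accumulate(x, dx)

    return _node(out, (x,), backward)


def embedding(codes: np.ndarray, table: Tensor, freeze_rows: Sequence[int] = ()) -> Tensor:
    """Look up integer codes in an embedding table.

    ``codes``: (batch, L) integers; ``table``: (vocab, dim).  Output is
    channels-first, (batch, dim, L).  Rows listed in ``freeze_rows``
    (e.g. the padding symbol) receive no gradient.
    """
    codes = np.asarray(codes)
    if codes.min() < 0 or codes.max() >= table.data.shape[0]:
        raise IndexError("code outside the embedding vocabulary")
    out = table.data[codes].transpose(0, 2, 1)

    def backward(g):
        if _wants_grad(table):
            dt = np.zeros_like(table.data)
            np.add.at(dt, codes.ravel(), g.transpose(0, 2, 1).reshape(-1, table.data.shape[1]))
            for r in freeze_rows:
                dt[r] = 0.0
            _accumulate(table, dt)

    return _node(out, (table,), backward)
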