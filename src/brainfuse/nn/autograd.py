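"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based autograd: each :class:`Tensor` wraps an
``ndarray`` and remembers, for every parent it was computed from, a closure
that maps the output gradient to that parent's gradient. ``backward()``
walks the graph in reverse topological order and accumulates gradients.

Only the operations needed by the model family in this package are
implemented (dense/batched matmul, broadcast arithmetic, reductions,
reshaping, convolutions live in :mod:`brainfuse.nn.layers`). Gradients are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "concatenate", "softmax"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum away extra leading axes
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from size 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the bookkeeping needed for reverse-mode differentiation."""

    __slots__ = ("data", "grad", "requires_grad", "_links")

    def __init__(self, data, requires_grad: bool = False):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        # list of (parent Tensor, fn: out_grad -> parent_grad)
        self._links = ()

    # -- construction helper used by every op ---------------------------------
    @staticmethod
    def _make(data, links):
        links = tuple((p, fn) for p, fn in links if p.requires_grad)
        out = Tensor(data, requires_grad=bool(links) and grad_enabled())
        if out.requires_grad:
            out._links = links
        return out

    # -- basic introspection ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- backward --------------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for parent, _ in node._links:
                if id(parent) not in seen:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            g = node.grad
            if g is None:
                continue
            for parent, fn in node._links:
                pg = fn(g)
                if parent.grad is None:
                    parent.grad = pg
                else:
                    parent.grad = parent.grad + pg

    # -- arithmetic --------------------------------------------------------------
    # Python scalars are kept as scalars (not wrapped into 0-d float64
    # arrays), so float32 graphs stay float32 under NEP 50 promotion.
    def __add__(self, other):
        if not isinstance(other, Tensor):
            return Tensor._make(self.data + other, [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
            ])
        other = _as_tensor(other)
        out = self.data + other.data
        return Tensor._make(out, [
            (self, lambda g: _unbroadcast(g, self.data.shape)),
            (other, lambda g: _unbroadcast(g, other.data.shape)),
        ])

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if not isinstance(other, Tensor):
            return Tensor._make(self.data * other, [
                (self, lambda g: _unbroadcast(g * other, self.data.shape)),
            ])
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(a.data * b.data, [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ])

    __rmul__ = __mul__

    def __truediv__(self, other):
        if not isinstance(other, Tensor):
            return self * (1.0 / other)
        other = _as_tensor(other)
        a, b = self, other
        return Tensor._make(a.data / b.data, [
            (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape)),
        ])

    def __rtruediv__(self, other):
        if not isinstance(other, Tensor):
            out = other / self.data
            return Tensor._make(out, [
                (self, lambda g: _unbroadcast(-g * out / self.data,
                                              self.data.shape)),
            ])
        return other / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        if exponent == 2:  # avoid np.power, which is slow for large arrays
            out = self.data * self.data
            return Tensor._make(out, [(self, lambda g: g * (2.0 * self.data))])
        out = self.data ** exponent
        return Tensor._make(out, [
            (self, lambda g: g * exponent * self.data ** (exponent - 1)),
        ])

    def __matmul__(self, other):
        other = _as_tensor(other)
        a, b = self, other
        out = np.matmul(a.data, b.data)

        def grad_a(g):
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            return _unbroadcast(ga, a.data.shape)

        def grad_b(g):
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            return _unbroadcast(gb, b.data.shape)

        return Tensor._make(out, [(a, grad_a), (b, grad_b)])

    # -- elementwise nonlinearities ----------------------------------------------
    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, [(self, lambda g: g * (0.5 / out))])

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), [(self, lambda g: g * sign)])

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, [(self, lambda g: g * (1.0 - out * out))])

    # -- reductions ----------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            kshape = list(self.data.shape)
            for ax in _axes_tuple(axis, self.data.ndim):
                kshape[ax] = 1
            return np.broadcast_to(g.reshape(kshape), self.data.shape).copy()

        return Tensor._make(out, [(self, grad_fn)])

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            count = int(np.prod([self.data.shape[ax]
                                 for ax in _axes_tuple(axis, self.data.ndim)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def max(self, axis, keepdims: bool = False):
        m = np.max(self.data, axis=axis, keepdims=True)
        out = m if keepdims else m.reshape(
            np.max(self.data, axis=axis, keepdims=False).shape)

        def grad_fn(g):
            mask = (self.data == m)
            counts = mask.sum(axis=_axes_tuple(axis, self.data.ndim), keepdims=True)
            return mask * (g.reshape(m.shape) / counts)

        return Tensor._make(out, [(self, grad_fn)])

    # -- shape manipulation ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape),
                            [(self, lambda g: g.reshape(old))])

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inverse = np.argsort(axes)
        out = np.ascontiguousarray(self.data.transpose(axes))
        return Tensor._make(out, [(self, lambda g: g.transpose(inverse))])

    def __getitem__(self, idx):
        out = self.data[idx]

        def grad_fn(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return full

        return Tensor._make(out, [(self, grad_fn)])


class Parameter(Tensor):
    """A tensor that is optimized during training."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _axes_tuple(axis, ndim) -> tuple:
    if axis is None:
        return tuple(range(ndim))
    if isinstance(axis, int):
        axis = (axis,)
    return tuple(ax % ndim for ax in axis)


def concatenate(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    splits = np.cumsum([d.shape[axis] for d in datas])[:-1]

    links = []

    def make_fn(i):
        def fn(g):
            return np.split(g, splits, axis=axis)[i]
        return fn

    for i, t in enumerate(tensors):
        links.append((t, make_fn(i)))
    return Tensor._make(out, links)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shifting by the (detached) max leaves both value and gradient unchanged
    shift = Tensor(np.max(x.data, axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)
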