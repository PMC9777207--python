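"""Reverse-mode automatic differentiation on numpy arrays.

A compact tape-based engine in the micrograd lineage, with one extra property
this package depends on: vector-Jacobian products are themselves expressed as
graph operations, so ``grad(..., create_graph=True)`` returns differentiable
tensors and second-order quantities (the Wasserstein critic's gradient
penalty) backpropagate correctly to parameters.

Activation nonlinearities are piecewise linear (leaky ReLU realised as a
multiply by a constant sign mask), so their second derivative is zero almost
everywhere — the usual convention for double backprop through ReLU networks.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


class Tensor:
    """An n-d array node in the computation graph."""

    __slots__ = ("data", "requires_grad", "grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable | None = None

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(astensor(other)))

    def __rsub__(self, other):
        return add(astensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return mul(self, pow_const(astensor(other), -1.0))

    def __rtruediv__(self, other):
        return mul(astensor(other), pow_const(self, -1.0))

    def __pow__(self, p):
        return pow_const(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor], vjp: Callable) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED[-1] and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back to ``shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, d in enumerate(shape) if d == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != shape:
        g = reshape(g, shape)
    return g


# -- arithmetic primitives ---------------------------------------------------

def add(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(a.data + b.data, (a, b), vjp)


def neg(a) -> Tensor:
    a = astensor(a)
    return _node(-a.data, (a,), lambda g: (neg(g),))


def mul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)

    def vjp(g):
        return _unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)

    return _node(a.data * b.data, (a, b), vjp)


def pow_const(a, p: float) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (mul(g, mul(Tensor(p), pow_const(a, p - 1.0))),)

    return _node(a.data ** p, (a,), vjp)


def sqrt(a) -> Tensor:
    return pow_const(a, 0.5)


def exp(a) -> Tensor:
    a = astensor(a)
    out_data = np.exp(a.data)

    def vjp(g):
        return (mul(g, Tensor(out_data)),)

    return _node(out_data, (a,), vjp)


def log(a) -> Tensor:
    a = astensor(a)

    def vjp(g):
        return (mul(g, pow_const(a, -1.0)),)

    return _node(np.log(a.data), (a,), vjp)


def matmul(a, b) -> Tensor:
    a, b = astensor(a), astensor(b)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")

    def vjp(g):
        return matmul(g, transpose(b, (1, 0))), matmul(transpose(a, (1, 0)), g)

    return _node(a.data @ b.data, (a, b), vjp)


# -- shape primitives --------------------------------------------------------

def reshape(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, old),))


def transpose(a, axes) -> Tensor:
    a = astensor(a)
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def broadcast_to(a, shape) -> Tensor:
    a = astensor(a)
    old = a.shape
    return _node(
        np.broadcast_to(a.data, shape).copy(), (a,), lambda g: (_unbroadcast(g, old),)
    )


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [astensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def vjp(g):
        outs = []
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(int(lo), int(hi))
            outs.append(narrow(g, tuple(idx)))
        return tuple(outs)

    return _node(np.concatenate([t.data for t in ts], axis=axis), ts, vjp)


def narrow(a, idx: tuple) -> Tensor:
    """Slice-only indexing; the adjoint scatters back into zeros."""
    a = astensor(a)
    shape = a.shape

    def vjp(g):
        return (_scatter(g, shape, idx),)

    return _node(a.data[idx].copy(), (a,), vjp)


def _scatter(g, shape, idx) -> Tensor:
    g = astensor(g)

    def vjp(gg):
        return (narrow(gg, idx),)

    buf = np.zeros(shape)
    buf[idx] = g.data
    return _node(buf, (g,), vjp)


# -- reductions --------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    in_shape = a.shape

    if axis is None:
        ax = tuple(range(a.ndim))
    elif isinstance(axis, int):
        ax = (axis,)
    else:
        ax = tuple(axis)

    def vjp(g):
        if not keepdims:
            kshape = tuple(1 if i in ax else d for i, d in enumerate(in_shape))
            g = reshape(g, kshape)
        return (broadcast_to(g, in_shape),)

    return _node(a.data.sum(axis=axis, keepdims=keepdims), (a,), vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = astensor(a)
    n = a.size if axis is None else np.prod(
        [a.shape[i] for i in (np.atleast_1d(axis))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / float(n)))


def tmax(a, axis: int, keepdims=False) -> Tensor:
    """Max along one axis; ties share the gradient equally."""
    a = astensor(a)
    out_data = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out_data).astype(np.float64)
    mask /= mask.sum(axis=axis, keepdims=True)
    in_shape = a.shape

    def vjp(g):
        if not keepdims:
            kshape = tuple(
                1 if i == (axis % len(in_shape)) else d for i, d in enumerate(in_shape)
            )
            g = reshape(g, kshape)
        return (mul(broadcast_to(g, in_shape), Tensor(mask)),)

    return _node(
        out_data if keepdims else out_data.squeeze(axis=axis), (a,), vjp
    )


# -- nonlinearity ------------------------------------------------------------

def leaky_relu(a, slope: float = 0.2) -> Tensor:
    """LeakyReLU as multiplication by a frozen slope mask (exact a.e.)."""
    a = astensor(a)
    mask = np.where(a.data > 0.0, 1.0, slope)
    return mul(a, Tensor(mask))


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


def sigmoid(a) -> Tensor:
    a = astensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def vjp(g):
        return (mul(g, Tensor(out_data * (1.0 - out_data))),)

    return _node(out_data, (a,), vjp)


def softplus(a) -> Tensor:
    """log(1 + exp(a)), computed stably."""
    a = astensor(a)

    def vjp(g):
        return (mul(g, sigmoid(a)),)

    return _node(np.logaddexp(0.0, a.data), (a,), vjp)


def tanh(a) -> Tensor:
    a = astensor(a)
    out_data = np.tanh(a.data)

    def vjp(g):
        return (mul(g, Tensor(1.0 - out_data ** 2)),)

    return _node(out_data, (a,), vjp)


# -- convolution lowering ----------------------------------------------------

def _im2col_np(x, kh, kw, sh, sw, ph, pw):
    n, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    cols = np.empty((n, c, kh, kw, ho, wo))
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = x[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw]
    return cols.reshape(n, c * kh * kw, ho * wo)


def _col2im_np(cols, xshape, kh, kw, sh, sw, ph, pw):
    n, c, h, w = xshape
    hp, wp = h + 2 * ph, w + 2 * pw
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (w + 2 * pw - kw) // sw + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    x = np.zeros((n, c, hp, wp))
    for i in range(kh):
        for j in range(kw):
            x[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += cols[:, :, i, j]
    if ph or pw:
        x = x[:, :, ph : hp - ph, pw : wp - pw]
    return x


def im2col(a, kernel, stride=1, padding=0) -> Tensor:
    """Extract sliding patches: (N,C,H,W) -> (N, C*kh*kw, Ho*Wo). Linear."""
    a = astensor(a)
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    xshape = a.shape

    def vjp(g):
        return (col2im(g, xshape, (kh, kw), (sh, sw), (ph, pw)),)

    return _node(_im2col_np(a.data, kh, kw, sh, sw, ph, pw), (a,), vjp)


def col2im(a, xshape, kernel, stride=1, padding=0) -> Tensor:
    a = astensor(a)
    kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding

    def vjp(g):
        return (im2col(g, (kh, kw), (sh, sw), (ph, pw)),)

    return _node(_col2im_np(a.data, xshape, kh, kw, sh, sw, ph, pw), (a,), vjp)


# -- backward pass -----------------------------------------------------------

def _toposort(root: Tensor) -> list[Tensor]:
    order, seen, stack = [], set(), [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(
    output: Tensor,
    inputs: Sequence[Tensor],
    create_graph: bool = False,
    grad_output: Tensor | None = None,
) -> list[Tensor]:
    """Gradients of ``output`` w.r.t. ``inputs``.

    With ``create_graph=True`` the returned tensors carry their own graph, so
    scalar functions of them can be differentiated again.
    """
    if not output.requires_grad:
        return [Tensor(np.zeros(t.shape)) for t in inputs]
    seed = grad_output if grad_output is not None else Tensor(np.ones(output.shape))

    ctx = contextlib.nullcontext() if create_graph else no_grad()
    with ctx:
        grads: dict[int, Tensor] = {id(output): seed}
        for node in reversed(_toposort(output)):
            g = grads.get(id(node))
            if g is None or node._vjp is None:
                continue
            for parent, pg in zip(node._parents, node._vjp(g)):
                if pg is None or not parent.requires_grad:
                    continue
                acc = grads.get(id(parent))
                grads[id(parent)] = pg if acc is None else add(acc, pg)
        return [grads.get(id(t), Tensor(np.zeros(t.shape))) for t in inputs]


def backward(loss: Tensor, params: Sequence[Tensor]) -> None:
    """Populate ``p.grad`` (numpy) for each parameter from a scalar loss."""
    for p, g in zip(params, grad(loss, params)):
        p.grad = g.data if p.grad is None else p.grad + g.data
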