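"""Reverse-mode automatic differentiation on NumPy arrays.

A minimal tape-based engine sized for the small convolutional networks in
this package.  Every primitive's vector-Jacobian product (VJP) is itself
expressed in terms of traced primitives, so gradients are ordinary graph
nodes and gradients-of-gradients work out of the box.  That property is what
lets the Wasserstein critic's gradient penalty — a function of the critic's
input gradient — be differentiated again with respect to the critic weights
during training.

Conventions
-----------
* Arrays are float64 throughout.
* Image batches are ``(N, C, H, W)``.
* Convolution is built from :func:`im2col` / :func:`col2im`, a mutually
  adjoint pair of linear primitives, plus 2-D :func:`matmul`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "grad",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "power",
    "sqrt",
    "absolute",
    "relu",
    "leaky_relu",
    "matmul",
    "tsum",
    "tmean",
    "reshape",
    "transpose",
    "concat",
    "slice_axis",
    "im2col",
    "col2im",
]


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "parents", "vjp", "requires_grad")

    def __init__(self, data, parents=(), vjp=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.parents = tuple(parents)
        self.vjp = vjp
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in self.parents
        )

    # -- conveniences -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        """A leaf copy that blocks gradient flow."""
        return Tensor(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # operator sugar
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# broadcasting helper: reduce ``g`` back to ``shape`` (inverse of broadcast)
# ---------------------------------------------------------------------------

def _unbroadcast(g: Tensor, shape) -> Tensor:
    if g.shape == tuple(shape):
        return g
    extra = g.data.ndim - len(shape)
    if extra > 0:
        g = tsum(g, axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = tsum(g, axis=axes, keepdims=True)
    if g.shape != tuple(shape):
        g = reshape(g, shape)
    return g


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def neg(a) -> Tensor:
    a = as_tensor(a)
    return Tensor(-a.data, (a,), lambda g: (neg(g),))


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(mul(g, b), a.shape), _unbroadcast(mul(g, a), b.shape)),
    )


def div(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return Tensor(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(div(g, b), a.shape),
            _unbroadcast(neg(div(mul(g, a), mul(b, b))), b.shape),
        ),
    )


def power(a, p: float) -> Tensor:
    """Elementwise ``a ** p`` for a constant exponent."""
    a = as_tensor(a)
    p = float(p)
    return Tensor(
        a.data ** p,
        (a,),
        lambda g: (mul(g, mul(Tensor(np.float64(p)), power(a, p - 1.0))),),
    )


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def absolute(a) -> Tensor:
    a = as_tensor(a)
    sign = Tensor(np.sign(a.data))
    return Tensor(np.abs(a.data), (a,), lambda g: (mul(g, sign),))


def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = Tensor((a.data > 0).astype(np.float64))
    return Tensor(a.data * mask.data, (a,), lambda g: (mul(g, mask),))


def leaky_relu(a, slope: float = 0.2) -> Tensor:
    a = as_tensor(a)
    scale = Tensor(np.where(a.data > 0, 1.0, slope))
    return Tensor(a.data * scale.data, (a,), lambda g: (mul(g, scale),))


# ---------------------------------------------------------------------------
# shape primitives
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        gd = g
        if axis is not None and not keepdims:
            ax = (axis,) if isinstance(axis, int) else tuple(axis)
            shp = list(a.shape)
            for i in sorted(a_i % len(shp) for a_i in ax):
                shp[i] = 1
            gd = reshape(gd, tuple(shp))
        return (broadcast_to(gd, a.shape),)

    return Tensor(out, (a,), vjp)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        ax = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[i] for i in ax]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(np.float64(1.0 / n)))


def broadcast_to(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    if a.shape == shape:
        return a
    return Tensor(
        np.broadcast_to(a.data, shape),
        (a,),
        lambda g: (_unbroadcast(g, a.shape),),
    )


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    shape = tuple(shape)
    return Tensor(
        a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),)
    )


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    return Tensor(
        a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),)
    )


def concat(tensors, axis: int) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.concatenate([[0], np.cumsum(sizes)])

    def vjp(g):
        return tuple(
            slice_axis(g, axis, int(offsets[i]), int(offsets[i + 1]))
            for i in range(len(tensors))
        )

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), vjp
    )


def slice_axis(a, axis: int, start: int, stop: int) -> Tensor:
    a = as_tensor(a)
    idx = [slice(None)] * a.data.ndim
    idx[axis] = slice(start, stop)
    idx = tuple(idx)
    return Tensor(
        a.data[idx],
        (a,),
        lambda g: (_pad_axis(g, axis, start, a.shape[axis] - stop),),
    )


def _pad_axis(a: Tensor, axis: int, before: int, after: int) -> Tensor:
    """Zero-pad along one axis — the linear adjoint of :func:`slice_axis`."""
    a = as_tensor(a)
    pads = [(0, 0)] * a.data.ndim
    pads[axis] = (before, after)
    n = a.shape[axis]
    return Tensor(
        np.pad(a.data, pads),
        (a,),
        lambda g: (slice_axis(g, axis, before, before + n),),
    )


# ---------------------------------------------------------------------------
# matmul (2-D only; batched cases are composed via reshape)
# ---------------------------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul primitive is 2-D; reshape batched operands first")
    return Tensor(
        a.data @ b.data,
        (a, b),
        lambda g: (
            matmul(g, transpose(b, (1, 0))),
            matmul(transpose(a, (1, 0)), g),
        ),
    )


# ---------------------------------------------------------------------------
# im2col / col2im: mutually adjoint linear maps underlying convolution
# ---------------------------------------------------------------------------

def _conv_out_size(h: int, k: int, stride: int, pad: int) -> int:
    return (h + 2 * pad - k) // stride + 1


def _im2col_data(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    n, c, h, w = x.shape
    oh = _conv_out_size(h, k, stride, pad)
    ow = _conv_out_size(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, oh, ow, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[2], s[3]),
        writeable=False,
    )
    # (N, OH, OW, C, k, k) -> (N*OH*OW, C*k*k)
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * oh * ow, c * k * k
    )


def _col2im_data(
    cols: np.ndarray, x_shape, k: int, stride: int, pad: int
) -> np.ndarray:
    n, c, h, w = x_shape
    oh = _conv_out_size(h, k, stride, pad)
    ow = _conv_out_size(w, k, stride, pad)
    cols6 = cols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += (
                cols6[:, :, :, :, i, j]
            )
    if pad:
        return xp[:, :, pad : pad + h, pad : pad + w]
    return xp


def im2col(x, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Unfold ``(N, C, H, W)`` into ``(N*OH*OW, C*k*k)`` patch rows."""
    x = as_tensor(x)
    shape = x.shape
    return Tensor(
        _im2col_data(x.data, k, stride, pad),
        (x,),
        lambda g: (col2im(g, shape, k, stride, pad),),
    )


def col2im(cols, x_shape, k: int, stride: int = 1, pad: int = 0) -> Tensor:
    """Adjoint of :func:`im2col` (overlap-add fold back to images)."""
    cols = as_tensor(cols)
    x_shape = tuple(x_shape)
    return Tensor(
        _col2im_data(cols.data, x_shape, k, stride, pad),
        (cols,),
        lambda g: (im2col(g, k, stride, pad),),
    )


# ---------------------------------------------------------------------------
# reverse-mode driver
# ---------------------------------------------------------------------------

def grad(output: Tensor, wrt) -> list:
    """Gradients of a scalar ``output`` with respect to each tensor in ``wrt``.

    The returned gradients are themselves graph nodes, so expressions built
    from them can be differentiated again (double backprop).
    Tensors in ``wrt`` that the output does not depend on get zero gradients.
    """
    if output.size != 1:
        raise ValueError("grad expects a scalar output")

    # topological order over the subgraph that requires grad
    topo: list[Tensor] = []
    seen = set()

    def visit(node: Tensor):
        stack = [(node, iter(node.parents))]
        seen.add(id(node))
        while stack:
            n, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen and p.requires_grad:
                    seen.add(id(p))
                    stack.append((p, iter(p.parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(n)
                stack.pop()

    if output.requires_grad:
        visit(output)

    wanted = {id(w) for w in wrt}
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones_like(output.data))}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if id(node) in wanted:
            grads[id(node)] = g  # keep gradients of requested tensors
        if node.vjp is None:
            continue
        for parent, pg in zip(node.parents, node.vjp(g)):
            if pg is None or not parent.requires_grad:
                continue
            acc = grads.get(id(parent))
            grads[id(parent)] = pg if acc is None else add(acc, pg)

    out = []
    for w in wrt:
        g = grads.get(id(w))
        out.append(g if g is not None else Tensor(np.zeros_like(w.data)))
    return out
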