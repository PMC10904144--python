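"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module provides exactly the tensor operations the peptide classifier
needs — 2-D convolution (1-D as a special case), batch normalization,
max pooling, embedding lookup, dropout, dense layers and the usual
element-wise arithmetic — together with an Adam optimizer.  Everything is
float64 and single-threaded numpy, so training and inference are
bit-reproducible for a fixed seed.

Gradients are accumulated through a tape: every :class:`Tensor` produced by
an operation keeps references to its parents and a closure that maps the
output gradient to parent gradients.  ``Tensor.backward()`` runs the tape in
reverse topological order.  Intermediate tensors keep their ``grad`` after a
backward pass, which is what the Grad-CAM code relies on.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "relu",
    "sigmoid",
    "log",
    "clip",
    "power",
    "vsum",
    "vmean",
    "vmax",
    "reshape",
    "transpose",
    "concat",
    "conv2d",
    "max_pool2d",
    "batch_norm",
    "embedding",
    "dropout",
    "Adam",
]


class Tensor:
    """Node in the autodiff tape wrapping a float64 numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
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
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar -------------------------------------------------
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

    def __matmul__(self, other):
        return matmul(self, other)


class Parameter(Tensor):
    """Learnable tensor (requires_grad always on)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to ``shape`` (the reverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    out._backward = backward
    return out


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = backward
    return out


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1.0 - s))

    out._backward = backward
    return out


def log(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(np.log(x.data), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g / x.data)

    out._backward = backward
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through unclipped entries."""
    x = _as_tensor(x)
    mask = (x.data > lo) & (x.data < hi)
    out = Tensor(np.clip(x.data, lo, hi), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    out._backward = backward
    return out


def power(x: Tensor, exponent: float) -> Tensor:
    """Element-wise x**exponent for a scalar exponent (x must be positive
    when the exponent is fractional)."""
    x = _as_tensor(x)
    out = Tensor(x.data**exponent, parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * exponent * x.data ** (exponent - 1.0))

    out._backward = backward
    return out


def vsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(x.data.sum(axis=axis, keepdims=keepdims), parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())
            return
        if not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, axes)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    out._backward = backward
    return out


def vmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = _as_tensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(vsum(x, axis=axis, keepdims=keepdims), 1.0 / float(n))


def vmax(x: Tensor, axis: int) -> Tensor:
    """Max along one axis; gradient flows to the argmax entry (first on ties)."""
    x = _as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    out_data = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        np.put_along_axis(
            gx, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
        )
        x._accumulate(gx)

    out._backward = backward
    return out


def reshape(x: Tensor, shape) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(x.data.reshape(shape), parents=(x,))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(x.data.shape))

    out._backward = backward
    return out


def transpose(x: Tensor, axes) -> Tensor:
    x = _as_tensor(x)
    out = Tensor(x.data.transpose(axes), parents=(x,))
    inverse = np.argsort(axes)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.transpose(inverse))

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    out._backward = backward
    return out


# -- convolution -------------------------------------------------------


def _same_padding(k: int) -> tuple[int, int]:
    # total padding k-1, split with the extra cell on the right
    return (k - 1) // 2, k - 1 - (k - 1) // 2


def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int):
    B, C, H, W = x.shape
    pt, pb = _same_padding(kh)
    pl, pr = _same_padding(kw)
    xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    Ho = (H + pt + pb - kh) // sh + 1
    Wo = (W + pl + pr - kw) // sw + 1
    cols = np.empty((B, C, kh, kw, Ho, Wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw]
    return cols.reshape(B, C * kh * kw, Ho * Wo), (Ho, Wo), (pt, pb, pl, pr)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: tuple[int, int] = (1, 1)) -> Tensor:
    """'Same'-padded 2-D convolution (cross-correlation).

    ``x``: (B, C, H, W); ``w``: (O, C, kh, kw); ``b``: (O,).
    Output spatial size is ceil(H/stride), ceil(W/stride).
    """
    x, w, b = _as_tensor(x), _as_tensor(w), _as_tensor(b)
    B, C, H, W = x.data.shape
    O, Cw, kh, kw = w.data.shape
    if C != Cw:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    sh, sw = stride
    cols, (Ho, Wo), (pt, pb, pl, pr) = _im2col(x.data, kh, kw, sh, sw)
    wf = w.data.reshape(O, C * kh * kw)
    out_data = (wf @ cols).reshape(B, O, Ho, Wo) + b.data[None, :, None, None]
    out = Tensor(out_data, parents=(x, w, b))

    def backward(g):
        gf = g.reshape(B, O, Ho * Wo)
        if b.requires_grad:
            b._accumulate(gf.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = np.einsum("bop,bkp->ok", gf, cols, optimize=True)
            w._accumulate(gw.reshape(O, C, kh, kw))
        if x.requires_grad:
            dcols = (wf.T @ gf).reshape(B, C, kh, kw, Ho, Wo)
            dxp = np.zeros((B, C, H + pt + pb, W + pl + pr))
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += dcols[:, :, i, j]
            x._accumulate(dxp[:, :, pt : pt + H, pl : pl + W])

    out._backward = backward
    return out


def max_pool2d(x: Tensor, kernel: tuple[int, int]) -> Tensor:
    """Non-overlapping max pooling with ceil-mode (-inf padding)."""
    x = _as_tensor(x)
    B, C, H, W = x.data.shape
    kh, kw = kernel
    Ho, Wo = -(-H // kh), -(-W // kw)
    xp = np.full((B, C, Ho * kh, Wo * kw), -np.inf)
    xp[:, :, :H, :W] = x.data
    windows = xp.reshape(B, C, Ho, kh, Wo, kw).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, Ho, Wo, kh * kw
    )
    idx = np.argmax(windows, axis=-1)
    out = Tensor(np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0], parents=(x,))

    def backward(g):
        if not x.requires_grad:
            return
        gw = np.zeros_like(windows)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gxp = gw.reshape(B, C, Ho, Wo, kh, kw).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, Ho * kh, Wo * kw
        )
        x._accumulate(gxp[:, :, :H, :W])

    out._backward = backward
    return out


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (B, C, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in evaluation mode the frozen running buffers are used
    (the op is then affine, so inference is deterministic).
    """
    x = _as_tensor(x)
    axes = (0, 2, 3)
    gb = gamma.data[None, :, None, None]
    bb = beta.data[None, :, None, None]
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
        std = np.sqrt(var + eps)[None, :, None, None]
        xhat = (x.data - mu[None, :, None, None]) / std
        out = Tensor(gb * xhat + bb, parents=(x, gamma, beta))
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate((g * xhat).sum(axis=axes))
            if beta.requires_grad:
                beta._accumulate(g.sum(axis=axes))
            if x.requires_grad:
                gxh = g * gb
                x._accumulate(
                    (
                        gxh
                        - gxh.mean(axis=axes, keepdims=True)
                        - xhat * (gxh * xhat).mean(axis=axes, keepdims=True)
                    )
                    / std
                )

        out._backward = backward
        return out

    std = np.sqrt(running_var + eps)[None, :, None, None]
    xhat = (x.data - running_mean[None, :, None, None]) / std
    out = Tensor(gb * xhat + bb, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accumulate(g.sum(axes))
        if x.requires_grad:
            x._accumulate(g * gb / std)

    out._backward = backward
    return out


def embedding(table: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup into an embedding table; gradient is scatter-added."""
    indices = np.asarray(indices)
    out = Tensor(table.data[indices], parents=(table,))

    def backward(g):
        if table.requires_grad:
            gt = np.zeros_like(table.data)
            np.add.at(gt, indices.reshape(-1), g.reshape(-1, table.data.shape[1]))
            table._accumulate(gt)

    out._backward = backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return mul(x, Tensor(mask))


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: Iterable[Parameter],
        lr: float,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / (1.0 - self.b1**self.t)
            vhat = self.v[i] / (1.0 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
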