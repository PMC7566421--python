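"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine sufficient for the convolutional / recurrent
models in this package: broadcasting arithmetic, matrix products,
2-D convolution and pooling, the usual activations, and a numerically
stable binary cross-entropy on logits.  Everything is float32 unless the
caller says otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "sigmoid",
    "tanh",
    "relu",
    "conv2d",
    "maxpool2d",
    "global_avg_pool",
    "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Gradients are accumulated on every node reached by :meth:`backward`,
    which lets callers inspect intermediate gradients (used for Grad-CAM).
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    # -- arithmetic ----------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        a, b = self, self._wrap(other)

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        a = self
        old = a.shape

        def backward(g):
            if a.requires_grad:
                a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        a = self

        def backward(g):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accum(g[tuple(idx)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


# -- activations -------------------------------------------------------

def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        if x.requires_grad:
            x._accum(g * s * (1.0 - s))

    return x._make(s, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    t = np.tanh(x.data)

    def backward(g):
        if x.requires_grad:
            x._accum(g * (1.0 - t * t))

    return x._make(t, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return x._make(x.data * mask, (x,), backward)


# -- convolution and pooling ------------------------------------------
# Layout is channels-last: (batch, height, width, channels).

def _pad_amount(size: int, k: int, stride: int, padding: str) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + k - size, 0)
    return total // 2, total - total // 2


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: str = "same") -> Tensor:
    """2-D convolution, implemented as a sum of shifted matrix products.

    `w` has shape (kh, kw, c_in, c_out).  One matmul per kernel tap keeps
    memory bounded without an explicit im2col buffer.
    """
    B, H, W, C = x.shape
    kh, kw, cin, cout = w.shape
    if cin != C:
        raise ValueError(f"channel mismatch: input has {C}, kernel expects {cin}")
    pt, pb = _pad_amount(H, kh, stride, padding)
    pl, pr = _pad_amount(W, kw, stride, padding)
    xp = np.pad(x.data, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
    Hp, Wp = xp.shape[1:3]
    OH = (Hp - kh) // stride + 1
    OW = (Wp - kw) // stride + 1
    needs_grad = x.requires_grad or w.requires_grad or (
        b is not None and b.requires_grad)
    out = np.zeros((B, OH, OW, cout), dtype=np.float32)
    out_flat = out.reshape(-1, cout)
    cols = {}  # contiguous input patches, reused by the backward pass
    for i in range(kh):
        for j in range(kw):
            patch = np.ascontiguousarray(
                xp[:, i:i + OH * stride:stride, j:j + OW * stride:stride, :]
            ).reshape(-1, C)
            if needs_grad:
                cols[i, j] = patch
            out_flat += patch @ w.data[i, j]
    if b is not None:
        out += b.data

    def backward(g):
        g2 = g.reshape(-1, cout)
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                if w.requires_grad:
                    w._accum_slice((i, j), cols[i, j].T @ g2)
                if x.requires_grad:
                    dxp[:, i:i + OH * stride:stride, j:j + OW * stride:stride, :] += (
                        g2 @ w.data[i, j].T
                    ).reshape(B, OH, OW, C)
        if x.requires_grad:
            x._accum(dxp[:, pt:Hp - pb or None, pl:Wp - pr or None, :])
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 1, 2)))

    parents = (x, w) if b is None else (x, w, b)
    res = x._make(out.reshape(B, OH, OW, cout), parents, backward)
    return res


def _accum_slice(self: Tensor, idx, grad) -> None:
    if self.grad is None:
        self.grad = np.zeros_like(self.data)
    self.grad[idx] += grad


Tensor._accum_slice = _accum_slice  # kernel-tap accumulation for conv2d


def maxpool2d(x: Tensor, pool: int = 2, stride: int | None = None) -> Tensor:
    """Max pooling.  Fast path when windows do not overlap."""
    stride = pool if stride is None else stride
    B, H, W, C = x.shape
    if stride == pool and H % pool == 0 and W % pool == 0:
        OH, OW = H // pool, W // pool
        view = x.data.reshape(B, OH, pool, OW, pool, C)
        cols = view.transpose(0, 1, 3, 5, 2, 4).reshape(B, OH, OW, C, pool * pool)
        arg = cols.argmax(axis=-1)
        out = np.take_along_axis(cols, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            if not x.requires_grad:
                return
            dcols = np.zeros_like(cols)
            np.put_along_axis(dcols, arg[..., None], g[..., None], axis=-1)
            dx = dcols.reshape(B, OH, OW, C, pool, pool).transpose(0, 1, 4, 2, 5, 3)
            x._accum(dx.reshape(B, H, W, C))

        return x._make(out, (x,), backward)

    # overlapping windows (used by the large backbone, inference only)
    OH = (H - pool) // stride + 1
    OW = (W - pool) // stride + 1
    stacked = np.stack([
        x.data[:, i:i + OH * stride:stride, j:j + OW * stride:stride, :]
        for i in range(pool) for j in range(pool)
    ])
    arg = stacked.argmax(axis=0)
    out = stacked.max(axis=0)

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for n, (i, j) in enumerate((i, j) for i in range(pool) for j in range(pool)):
            mask = arg == n
            sub = dx[:, i:i + OH * stride:stride, j:j + OW * stride:stride, :]
            np.add.at(sub, mask.nonzero(), g[mask])
        x._accum(dx)

    return x._make(out, (x,), backward)


def avgpool2d_same(x: Tensor, pool: int = 3) -> Tensor:
    """Stride-1 'same' average pooling (zero-padded borders)."""
    B, H, W, C = x.shape
    p = pool // 2
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros_like(x.data)
    for i in range(pool):
        for j in range(pool):
            out += xp[:, i:i + H, j:j + W, :]
    out /= pool * pool

    def backward(g):
        if not x.requires_grad:
            return
        gp = np.pad(g, ((0, 0), (p, p), (p, p), (0, 0))) / (pool * pool)
        dx = np.zeros_like(x.data)
        for i in range(pool):
            for j in range(pool):
                dx += gp[:, i:i + H, j:j + W, :]
        x._accum(dx)

    return x._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, H, W, C) -> (B, C), averaging over the spatial grid."""
    B, H, W, C = x.shape
    out = x.data.mean(axis=(1, 2))

    def backward(g):
        if x.requires_grad:
            x._accum(np.broadcast_to(g[:, None, None, :] / (H * W), x.shape).copy())

    return x._make(out, (x,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float32).reshape(z.shape)
    loss = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accum(g * (p - y) / n)

    return logits._make(np.float32(loss.mean()), (logits,), backward)
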