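"""Minimal reverse-mode autodiff on numpy arrays.

Implements exactly the operations the segmentation head needs: dilated 2-D
convolution, batch normalization, ReLU/sigmoid gates, channel concatenation,
axis means with broadcasting, bilinear resizing and softmax cross-entropy.
Everything is float32 and single-threaded, so runs are bit-reproducible for a
fixed seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "concat",
    "mean_axis",
    "broadcast_to",
    "conv2d",
    "batchnorm2d",
    "bilinear_resize",
    "cross_entropy",
]


class Tensor:
    """An array node in the computation graph.

    ``requires_grad`` marks leaves that accumulate gradients; interior nodes
    record a backward closure and their parents.
    """

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

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) node, seeding with ones."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators used in a few places
    def __add__(self, other: "Tensor") -> "Tensor":
        return add(self, other)

    def __mul__(self, other: "Tensor") -> "Tensor":
        return mul(self, other)


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
        out.requires_grad = True
    return out


def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _node(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(a.data * b.data, (a, b), bw)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return _node(x.data * mask, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accum(g * s * (1.0 - s))

    return _node(s, (x,), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


def mean_axis(x: Tensor, axis: int) -> Tensor:
    """Mean over one axis, keeping it as size 1 (used by strip pooling)."""
    n = x.data.shape[axis]

    def bw(g):
        x._accum(np.broadcast_to(g / n, x.data.shape))

    return _node(x.data.mean(axis=axis, keepdims=True), (x,), bw)


def broadcast_to(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    def bw(g):
        x._accum(_unbroadcast(g, x.data.shape))

    return _node(np.broadcast_to(x.data, shape).copy(), (x,), bw)


def conv2d(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: tuple[int, int] = (1, 1),
    dilation: tuple[int, int] = (1, 1),
    padding: tuple[int, int] | None = None,
) -> Tensor:
    """2-D convolution with per-axis dilation; default padding keeps size at stride 1.

    ``x``: (N, Cin, H, W); ``w``: (Cout, Cin, Kh, Kw); ``b``: (Cout,) or None.
    Implemented as a sum over kernel taps, each a tensordot on a strided slice —
    fast enough at desk scale and with an exactly symmetric backward pass.
    """
    sh, sw = stride
    dh, dw = dilation
    kh, kw = w.data.shape[2], w.data.shape[3]
    if padding is None:
        padding = (dh * (kh - 1) // 2, dw * (kw - 1) // 2)
    ph, pw = padding
    n, cin, h, wdt = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - dh * (kh - 1) - 1) // sh + 1
    wo = (wp - dw * (kw - 1) - 1) // sw + 1
    cout = w.data.shape[0]
    y = np.zeros((n, cout, ho, wo), dtype=np.float32)
    for a in range(kh):
        for c in range(kw):
            sl = xp[:, :, a * dh : a * dh + sh * (ho - 1) + 1 : sh,
                    c * dw : c * dw + sw * (wo - 1) + 1 : sw]
            y += np.einsum("oc,nchw->nohw", w.data[:, :, a, c], sl, optimize=True)
    if b is not None:
        y += b.data[None, :, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(w.data)
        for a in range(kh):
            for c in range(kw):
                sl = xp[:, :, a * dh : a * dh + sh * (ho - 1) + 1 : sh,
                        c * dw : c * dw + sw * (wo - 1) + 1 : sw]
                gw[:, :, a, c] = np.einsum("nohw,nchw->oc", g, sl, optimize=True)
                gxp[:, :, a * dh : a * dh + sh * (ho - 1) + 1 : sh,
                    c * dw : c * dw + sw * (wo - 1) + 1 : sw] += np.einsum(
                    "oc,nohw->nchw", w.data[:, :, a, c], g, optimize=True)
        gx = gxp[:, :, ph : ph + h, pw : pw + wdt] if (ph or pw) else gxp
        x._accum(gx)
        w._accum(gw)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))

    return _node(y, parents, bw)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W)."""
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    std = np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) / std[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    cnt = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def bw(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        beta._accum(g.sum(axis=(0, 2, 3)))
        dxhat = g * gamma.data[None, :, None, None]
        if training:
            # standard batchnorm backward through the batch statistics
            sum_dxhat = dxhat.sum(axis=(0, 2, 3))
            sum_dxhat_xhat = (dxhat * xhat).sum(axis=(0, 2, 3))
            gx = (
                dxhat
                - sum_dxhat[None, :, None, None] / cnt
                - xhat * sum_dxhat_xhat[None, :, None, None] / cnt
            ) / std[None, :, None, None]
        else:
            gx = dxhat / std[None, :, None, None]
        x._accum(gx)

    return _node(y, (x, gamma, beta), bw)


def _resize_weights(n_in: int, n_out: int):
    """Half-pixel-center source coordinates, clipped to the valid range."""
    src = (np.arange(n_out, dtype=np.float64) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(np.intp)
    i1 = np.minimum(i0 + 1, n_in - 1)
    t = (src - i0).astype(np.float32)
    return i0, i1, t


def bilinear_resize(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear interpolation to (out_h, out_w), half-pixel convention."""
    n, c, h, w = x.data.shape
    i0, i1, ti = _resize_weights(h, out_h)
    j0, j1, tj = _resize_weights(w, out_w)
    wi0, wi1 = (1.0 - ti)[:, None], ti[:, None]
    wj0, wj1 = (1.0 - tj)[None, :], tj[None, :]
    corners = (
        (i0, j0, wi0 * wj0),
        (i0, j1, wi0 * wj1),
        (i1, j0, wi1 * wj0),
        (i1, j1, wi1 * wj1),
    )
    y = np.zeros((n, c, out_h, out_w), dtype=np.float32)
    for ii, jj, wgt in corners:
        y += x.data[:, :, ii[:, None], jj[None, :]] * wgt

    def bw(g):
        gx = np.zeros_like(x.data)
        for ii, jj, wgt in corners:
            np.add.at(
                gx,
                (slice(None), slice(None), ii[:, None], jj[None, :]),
                g * wgt,
            )
        x._accum(gx)

    return _node(y, (x,), bw)


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; ``logits`` (N, C, H, W), ``target`` (N, H, W) ints."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n, c, h, w = p.shape
    idx_n, idx_h, idx_w = np.ix_(np.arange(n), np.arange(h), np.arange(w))
    picked = p[idx_n, target, idx_h, idx_w]
    loss = -np.log(np.maximum(picked, 1e-12)).mean()
    cnt = n * h * w

    def bw(g):
        grad = p.copy()
        onehot = np.zeros_like(grad)
        onehot[idx_n, target, idx_h, idx_w] = 1.0
        grad = (grad - onehot) * (g / cnt)
        logits._accum(grad)

    return _node(np.float32(loss), (logits,), bw)
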