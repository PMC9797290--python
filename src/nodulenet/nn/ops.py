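"""Differentiable primitives: each forward returns a Tensor wired with a
hand-written backward closure.

Convolutions use strided sliding-window views plus einsum; the input
gradient of a strided convolution is computed as the full correlation of the
stride-dilated output gradient with the flipped kernel (the standard
transposed-convolution identity). Max pooling is restricted to
kernel == stride (non-overlapping), which is all the package's networks use.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, as_tensor

__all__ = [
    "add",
    "mul",
    "matmul",
    "relu",
    "sigmoid",
    "reshape",
    "flatten",
    "take_rows",
    "transpose",
    "concat_rows",
    "stack0",
    "conv_nd",
    "conv_transpose2x",
    "maxpool_nd",
    "dropout",
    "roi_pool",
    "softmax",
    "softmax_cross_entropy",
    "bce_with_logits",
    "smooth_l1",
    "mean_",
    "sum_",
]


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b) -> Tensor:
    a = as_tensor(a)
    b = as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def mul(a: Tensor, b) -> Tensor:
    a = as_tensor(a)
    b = as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = x.data * mask

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))

    def backward(g):
        if x.requires_grad:
            x._accumulate(g * s * (1 - s))

    return Tensor(s, parents=(x,), backward=backward)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.reshape(orig))

    return Tensor(out_data, parents=(x,), backward=backward)


def flatten(x: Tensor) -> Tensor:
    """Flatten all but the leading (batch) axis."""
    return reshape(x, (x.data.shape[0], -1))


def take_rows(x: Tensor, indices: np.ndarray) -> Tensor:
    """Gather rows along axis 0 (scatter-add on the way back)."""
    indices = np.asarray(indices, dtype=np.intp)
    out_data = x.data[indices]

    def backward(g):
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, indices, g)
            x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def transpose(x: Tensor, axes: Sequence[int]) -> Tensor:
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out_data = x.data.transpose(axes)

    def backward(g):
        if x.requires_grad:
            x._accumulate(g.transpose(inv))

    return Tensor(out_data, parents=(x,), backward=backward)


def concat_rows(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate along axis 0 (tensors may differ in leading length)."""
    sizes = [t.data.shape[0] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=0)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t._accumulate(g[a:b])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def stack0(tensors: Sequence[Tensor]) -> Tensor:
    out_data = np.stack([t.data for t in tensors])

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(g[i])

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


# ---------------------------------------------------------------------------
# Convolution
# ---------------------------------------------------------------------------

def _window_axes(nd: int) -> tuple[int, ...]:
    return tuple(range(2, 2 + nd))


def conv_nd(
    x: Tensor,
    w: Tensor,
    b: Tensor | None,
    stride: Sequence[int],
    pad: Sequence[int],
) -> Tensor:
    """N-dimensional cross-correlation.

    ``x``: (N, C, *spatial); ``w``: (F, C, *kernel); ``b``: (F,) or None.
    """
    nd = x.data.ndim - 2
    stride = tuple(stride)
    pad = tuple(pad)
    ksize = w.data.shape[2:]
    pad_width = [(0, 0), (0, 0)] + [(p, p) for p in pad]
    xp = np.pad(x.data, pad_width)
    win = sliding_window_view(xp, ksize, axis=_window_axes(nd))
    slicer = (slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)
    win = win[slicer]  # (N, C, *out, *kernel)
    sub_in = "nc" + "".join("xyz"[:nd]) + "".join("uvw"[:nd])
    sub_w = "fc" + "".join("uvw"[:nd])
    sub_out = "nf" + "".join("xyz"[:nd])
    out_data = np.einsum(f"{sub_in},{sub_w}->{sub_out}", win, w.data, optimize=True)
    if b is not None:
        out_data += b.data.reshape((1, -1) + (1,) * nd)

    out_spatial = out_data.shape[2:]
    in_spatial = x.data.shape[2:]

    def backward(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0,) + _window_axes(nd)))
        if w.requires_grad:
            w._accumulate(
                np.einsum(f"{sub_in},{sub_out}->{sub_w}", win, g, optimize=True)
            )
        if x.requires_grad:
            # dilate g by the stride, right-pad the alignment remainder,
            # then full-correlate with the flipped kernel.
            dil_shape = tuple(
                (o - 1) * s + 1 for o, s in zip(out_spatial, stride)
            )
            extra = tuple(
                i + 2 * p - k - (o - 1) * s
                for i, p, k, o, s in zip(in_spatial, pad, ksize, out_spatial, stride)
            )
            gd = np.zeros(g.shape[:2] + dil_shape, dtype=g.dtype)
            gd[(slice(None), slice(None)) + tuple(slice(None, None, s) for s in stride)] = g
            pw = [(0, 0), (0, 0)] + [
                (k - 1, k - 1 + e) for k, e in zip(ksize, extra)
            ]
            gdp = np.pad(gd, pw)
            wf = w.data[(slice(None), slice(None)) + (slice(None, None, -1),) * nd]
            win_g = sliding_window_view(gdp, ksize, axis=_window_axes(nd))
            sub_gin = "nf" + "".join("xyz"[:nd]) + "".join("uvw"[:nd])
            dxp = np.einsum(f"{sub_gin},{sub_w}->nc" + "xyz"[:nd], win_g, wf, optimize=True)
            crop = (slice(None), slice(None)) + tuple(
                slice(p, p + i) for p, i in zip(pad, in_spatial)
            )
            x._accumulate(dxp[crop])

    return Tensor(out_data, parents=(x, w) + ((b,) if b is not None else ()), backward=backward)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Learnable x2 upsampling: transposed conv with kernel 2, stride 2.

    ``x``: (N, C, H, W); ``w``: (C, F, 2, 2); output (N, F, 2H, 2W).
    """
    n, c, h, wd = x.data.shape
    f = w.data.shape[1]
    out_data = np.einsum("nchw,cfab->nfhawb", x.data, w.data, optimize=True).reshape(
        n, f, 2 * h, 2 * wd
    )
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1)

    def backward(g):
        gr = g.reshape(n, f, h, 2, wd, 2).transpose(0, 1, 2, 4, 3, 5)  # n f h w a b
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nchw,nfhwab->cfab", x.data, gr, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("nfhwab,cfab->nchw", gr, w.data, optimize=True))

    return Tensor(out_data, parents=(x, w) + ((b,) if b is not None else ()), backward=backward)


def maxpool_nd(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling (kernel == stride); kernel 1 is identity."""
    if kernel == 1:
        return reshape(x, x.data.shape)
    nd = x.data.ndim - 2
    spatial = x.data.shape[2:]
    if any(s % kernel for s in spatial):
        raise ValueError(f"spatial shape {spatial} not divisible by pool kernel {kernel}")
    out_spatial = tuple(s // kernel for s in spatial)
    new_shape = x.data.shape[:2] + tuple(
        v for s in out_spatial for v in (s, kernel)
    )
    xr = x.data.reshape(new_shape)
    # move the kernel axes to the end
    perm = (0, 1) + tuple(2 + 2 * i for i in range(nd)) + tuple(3 + 2 * i for i in range(nd))
    xr = xr.transpose(perm).reshape(x.data.shape[:2] + out_spatial + (kernel**nd,))
    idx = xr.argmax(axis=-1)
    out_data = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if x.requires_grad:
            gwin = np.zeros(xr.shape, dtype=g.dtype)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gwin = gwin.reshape(
                x.data.shape[:2] + out_spatial + (kernel,) * nd
            )
            inv = np.argsort(perm)
            gx = gwin.transpose(inv).reshape(x.data.shape)
            x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p == 0:
        return reshape(x, x.data.shape)
    mask = (rng.uniform(size=x.data.shape) >= p) / (1.0 - p)
    return mul(x, Tensor(mask.astype(x.data.dtype)))


def roi_pool(feat: Tensor, rois: np.ndarray, grid: int = 7) -> Tensor:
    """Max-pool each ROI of a (C, H, W) feature map into a (C, grid, grid) block.

    ``rois``: (R, 4) boxes in feature-map cell coordinates, half-open. Each
    ROI is divided into ``grid x grid`` bins; sub-cell (degenerate) bins fall
    back to the nearest single cell.
    """
    c, h, w = feat.data.shape
    rois = np.asarray(rois, dtype=float)
    if rois.ndim != 2 or rois.shape[1] != 4:
        raise ValueError("rois must be (R, 4)")
    if np.any(rois[:, 2] <= rois[:, 0]) or np.any(rois[:, 3] <= rois[:, 1]):
        raise ValueError("empty ROI")
    r = len(rois)
    out = np.empty((r, c, grid, grid), dtype=feat.data.dtype)
    # flat spatial index of the max cell for every output element
    argidx = np.empty((r, c, grid, grid), dtype=np.intp)
    flat = feat.data.reshape(c, -1)
    for ri, (x0, y0, x1, y1) in enumerate(rois):
        x0c, x1c = np.clip([x0, x1], 0, w)
        y0c, y1c = np.clip([y0, y1], 0, h)
        for gy in range(grid):
            ya = y0c + (y1c - y0c) * gy / grid
            yb = y0c + (y1c - y0c) * (gy + 1) / grid
            ia, ib = int(np.floor(ya)), int(np.ceil(yb))
            if ib <= ia:  # degenerate: nearest single cell
                ia = int(np.clip(round((ya + yb) / 2 - 0.5), 0, h - 1))
                ib = ia + 1
            ia, ib = max(0, min(ia, h - 1)), max(1, min(ib, h))
            for gx in range(grid):
                xa = x0c + (x1c - x0c) * gx / grid
                xb = x0c + (x1c - x0c) * (gx + 1) / grid
                ja, jb = int(np.floor(xa)), int(np.ceil(xb))
                if jb <= ja:
                    ja = int(np.clip(round((xa + xb) / 2 - 0.5), 0, w - 1))
                    jb = ja + 1
                ja, jb = max(0, min(ja, w - 1)), max(1, min(jb, w))
                block = feat.data[:, ia:ib, ja:jb].reshape(c, -1)
                k = block.argmax(axis=1)
                ky, kx = np.unravel_index(k, (ib - ia, jb - ja))
                argidx[ri, :, gy, gx] = (ia + ky) * w + (ja + kx)
                out[ri, :, gy, gx] = np.take_along_axis(block, k[:, None], 1)[:, 0]

    def backward(g):
        if feat.requires_grad:
            gf = np.zeros_like(flat)
            ch = np.arange(c)[None, :, None, None]
            np.add.at(
                gf,
                (np.broadcast_to(ch, argidx.shape).ravel(), argidx.ravel()),
                g.reshape(-1),
            )
            feat._accumulate(gf.reshape(feat.data.shape))

    return Tensor(out, parents=(feat,), backward=backward)


# ---------------------------------------------------------------------------
# Losses / reductions
# ---------------------------------------------------------------------------

def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * s).sum(axis=axis, keepdims=True)
            x._accumulate(s * (g - dot))

    return Tensor(s, parents=(x,), backward=backward)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of (N, K) logits against integer labels."""
    labels = np.asarray(labels, dtype=np.intp)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsum
    n = len(labels)
    loss = -logp[np.arange(n), labels].mean()

    def backward(g):
        if logits.requires_grad:
            grad = np.exp(logp)
            grad[np.arange(n), labels] -= 1.0
            logits._accumulate(g * grad / n)

    return Tensor(np.asarray(loss), parents=(logits,), backward=backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable form)."""
    t = np.asarray(targets, dtype=logits.data.dtype)
    z = logits.data
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            s = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            logits._accumulate(g * (s - t) / n)

    return Tensor(np.asarray(loss.mean()), parents=(logits,), backward=backward)


def smooth_l1(pred: Tensor, target: np.ndarray, beta: float = 1.0) -> Tensor:
    """Mean smooth-L1 (Huber) regression loss."""
    t = np.asarray(target, dtype=pred.data.dtype)
    d = pred.data - t
    ad = np.abs(d)
    loss = np.where(ad < beta, 0.5 * d**2 / beta, ad - 0.5 * beta)
    n = d.size

    def backward(g):
        if pred.requires_grad:
            grad = np.where(ad < beta, d / beta, np.sign(d))
            pred._accumulate(g * grad / n)

    return Tensor(np.asarray(loss.mean() if n else 0.0), parents=(pred,), backward=backward)


def mean_(x: Tensor) -> Tensor:
    n = x.data.size

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.full(x.data.shape, g / n, dtype=x.data.dtype))

    return Tensor(np.asarray(x.data.mean()), parents=(x,), backward=backward)


def sum_(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accumulate(np.full(x.data.shape, g, dtype=x.data.dtype))

    return Tensor(np.asarray(x.data.sum()), parents=(x,), backward=backward)
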