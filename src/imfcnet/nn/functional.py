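"""Differentiable operations on :class:`~imfcnet.nn.tensor.Tensor`.

Convolutions use kernel-offset accumulation: for every kernel offset
``(i, j)`` the padded input is sliced with the output stride and hit with a
single BLAS matmul.  This keeps memory at one input-sized buffer per offset
(no full im2col matrix) while staying matmul-bound, and the backward pass is
the exact mirror (strided slice ``+=``).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor

_f32 = np.float32


def _pair(v) -> tuple[int, int]:
    return (v, v) if isinstance(v, int) else (int(v[0]), int(v[1]))


def _norm_padding(padding) -> tuple[int, int, int, int]:
    """Normalize to (top, bottom, left, right).  Accepts an int, an (h, w)
    pair, or a ((top, bottom), (left, right)) pair of pairs."""
    if isinstance(padding, int):
        return padding, padding, padding, padding
    a, b = padding
    if isinstance(a, int) and isinstance(b, int):
        return a, a, b, b
    return int(a[0]), int(a[1]), int(b[0]), int(b[1])


def _pad_hw(x: np.ndarray, pads: tuple[int, int, int, int],
            value: float = 0.0) -> np.ndarray:
    if not any(pads):
        return x
    pt, pb, pl, pr = pads
    return np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)),
                  constant_values=value)


def same_padding(kernel: tuple[int, int]):
    """Padding giving 'same' output size at stride 1; even kernels pad
    asymmetrically (total k - 1, the extra row/column at the end)."""
    kh, kw = kernel
    return ((kh - 1) // 2, kh // 2), ((kw - 1) // 2, kw // 2)


# ---------------------------------------------------------------------------
# elementwise / shape ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    if a.shape != b.shape:
        raise ValueError(f"add expects equal shapes, got {a.shape} vs {b.shape}")
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return Tensor._make(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.maximum(x.data, _f32(0))

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * (x.data > 0))

    return Tensor._make(out_data, (x,), backward)


def relu6(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out_data = np.clip(x.data, 0, 6)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g * ((x.data > 0) & (x.data < 6)))

    return Tensor._make(out_data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    orig = x.data.shape
    out_data = x.data.reshape(shape)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g.reshape(orig))

    return Tensor._make(out_data, (x,), backward)


def flatten(x: Tensor) -> Tensor:
    return reshape(x, (x.shape[0], -1))


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t.accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# dense / conv ops
# ---------------------------------------------------------------------------

def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """``y = x @ w (+ b)`` with x: (N, F), w: (F, O), b: (O,)."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = x.data @ w.data
    if b is not None:
        out_data = out_data + b.data
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad:
            x.accumulate(g @ w.data.T)
        if w.requires_grad:
            w.accumulate(x.data.T @ g)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=0))

    return Tensor._make(out_data, parents, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=1, padding=0) -> Tensor:
    """2-D cross-correlation.  x: (N,C,H,W), w: (O,C,kh,kw), b: (O,)."""
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = _pair(stride)
    pads = _norm_padding(padding)
    pt, _, pl, _ = pads
    n, c, h, wd = x.shape
    o, cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {cw}")
    ho = (h + pads[0] + pads[1] - kh) // sh + 1
    wo = (wd + pads[2] + pads[3] - kw) // sw + 1
    if ho <= 0 or wo <= 0:
        raise ValueError(
            f"conv2d output would be empty: input {h}x{wd}, kernel {kh}x{kw}, "
            f"stride {sh}x{sw}, padding {pads}")
    pointwise = kh == kw == 1 and sh == sw == 1 and not any(pads)
    xp = _pad_hw(x.data, pads)
    if pointwise:
        y = np.matmul(w.data[:, :, 0, 0],
                      np.ascontiguousarray(xp).reshape(n, c, -1))
    else:
        y = np.zeros((n, o, ho * wo), dtype=_f32)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
                y += np.matmul(w.data[:, :, i, j],
                               np.ascontiguousarray(xs).reshape(n, c, -1))
    y = np.ascontiguousarray(y.reshape(n, o, ho, wo))
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gf = g.reshape(n, o, -1)
        if w.requires_grad or x.requires_grad:
            dxp = np.zeros_like(xp) if x.requires_grad else None
            dw = np.zeros_like(w.data) if w.requires_grad else None
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
                    if dw is not None:
                        dw[:, :, i, j] = np.einsum(
                            "nol,ncl->oc", gf, xs.reshape(n, c, -1),
                            optimize=True)
                    if dxp is not None:
                        dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += \
                            np.matmul(w.data[:, :, i, j].T, gf).reshape(
                                n, c, ho, wo)
            if dw is not None:
                w.accumulate(dw)
            if dxp is not None:
                x.accumulate(dxp[:, :, pt:pt + h, pl:pl + wd]
                             if any(pads) else dxp)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, backward)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=1, padding=0) -> Tensor:
    """Per-channel 2-D cross-correlation.  x: (N,C,H,W), w: (C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    sh, sw = _pair(stride)
    pads = _norm_padding(padding)
    pt, _, pl, _ = pads
    n, c, h, wd = x.shape
    cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"depthwise channel mismatch: input {c}, weight {cw}")
    ho = (h + pads[0] + pads[1] - kh) // sh + 1
    wo = (wd + pads[2] + pads[3] - kw) // sw + 1
    xp = _pad_hw(x.data, pads)
    y = np.zeros((n, c, ho, wo), dtype=_f32)
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
            y += xs * w.data[None, :, i, j, None, None]
    if b is not None:
        y += b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if x.requires_grad or w.requires_grad:
            dxp = np.zeros_like(xp) if x.requires_grad else None
            dw = np.zeros_like(w.data) if w.requires_grad else None
            for i in range(kh):
                for j in range(kw):
                    xs = xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
                    if dw is not None:
                        dw[:, i, j] = (g * xs).sum(axis=(0, 2, 3))
                    if dxp is not None:
                        dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += \
                            g * w.data[None, :, i, j, None, None]
            if dw is not None:
                w.accumulate(dw)
            if dxp is not None:
                x.accumulate(dxp[:, :, pt:pt + h, pl:pl + wd]
                             if any(pads) else dxp)
        if b is not None and b.requires_grad:
            b.accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(y, parents, backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def max_pool2d(x: Tensor, kernel, stride=None, padding=0) -> Tensor:
    x = as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    pads = _norm_padding(padding)
    pt, _, pl, _ = pads
    n, c, h, wd = x.shape
    ho = (h + pads[0] + pads[1] - kh) // sh + 1
    wo = (wd + pads[2] + pads[3] - kw) // sw + 1
    xp = _pad_hw(x.data, pads, value=-np.inf)
    y = np.full((n, c, ho, wo), -np.inf, dtype=_f32)
    arg = np.zeros((n, c, ho, wo), dtype=np.int16)
    for idx, (i, j) in enumerate((i, j) for i in range(kh) for j in range(kw)):
        xs = xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
        better = xs > y
        y = np.where(better, xs, y)
        arg = np.where(better, np.int16(idx), arg)

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        for idx, (i, j) in enumerate(
                (i, j) for i in range(kh) for j in range(kw)):
            dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += \
                g * (arg == idx)
        x.accumulate(dxp[:, :, pt:pt + h, pl:pl + wd]
                     if any(pads) else dxp)

    return Tensor._make(y, (x,), backward)


def avg_pool2d(x: Tensor, kernel, stride=None, padding=0) -> Tensor:
    """Average pooling; zero padding counts toward the divisor."""
    x = as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride if stride is not None else kernel)
    pads = _norm_padding(padding)
    pt, _, pl, _ = pads
    n, c, h, wd = x.shape
    ho = (h + pads[0] + pads[1] - kh) // sh + 1
    wo = (wd + pads[2] + pads[3] - kw) // sw + 1
    xp = _pad_hw(x.data, pads)
    y = np.zeros((n, c, ho, wo), dtype=_f32)
    for i in range(kh):
        for j in range(kw):
            y += xp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw]
    inv = _f32(1.0 / (kh * kw))
    y *= inv

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        gs = g * inv
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + sh * ho:sh, j:j + sw * wo:sw] += gs
        x.accumulate(dxp[:, :, pt:pt + h, pl:pl + wd]
                     if any(pads) else dxp)

    return Tensor._make(y, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) spatial mean."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    out_data = x.data.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            x.accumulate(np.broadcast_to(
                (g / (h * w))[:, :, None, None], x.shape).astype(_f32))

    return Tensor._make(out_data, (x,), backward)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1,
               eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, C, H, W) or (N, C).

    In training mode the batch statistics are used and the running buffers
    are updated in place (exponential moving average, unbiased variance in
    the buffer as is conventional).
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    nd = x.data.ndim
    axes = (0,) if nd == 2 else (0, 2, 3)
    shape = [1] * nd
    shape[1] = x.shape[1]
    m = float(np.prod([x.shape[a] for a in axes]))
    xr = np.ascontiguousarray(x.data).reshape(x.shape[0], x.shape[1], -1)
    if training:
        s1 = xr.sum(axis=(0, 2), dtype=np.float64)
        s2 = np.einsum("ncl,ncl->c", xr, xr, optimize=False)
        mean = s1 / m
        var = np.maximum(s2 / m - mean * mean, 0.0)
        if m > 1:
            running_mean *= (1 - momentum)
            running_mean += momentum * mean
            running_var *= (1 - momentum)
            running_var += momentum * var * (m / (m - 1))
    else:
        mean = running_mean.astype(np.float64)
        var = running_var.astype(np.float64)
    inv_std = 1.0 / np.sqrt(var + eps)
    # fused affine: out = a * x + c with per-channel a, c
    a = (gamma.data * inv_std).astype(_f32).reshape(shape)
    cc = (beta.data - gamma.data * mean * inv_std).astype(_f32).reshape(shape)
    out_data = x.data * a + cc

    def backward(g):
        mean32 = mean.astype(_f32).reshape(shape)
        istd32 = inv_std.astype(_f32).reshape(shape)
        xhat = (x.data - mean32) * istd32
        xhr = xhat.reshape(xr.shape)
        gr = np.ascontiguousarray(g).reshape(xr.shape)
        gdot = np.einsum("ncl,ncl->c", gr, xhr, optimize=False)
        if gamma.requires_grad:
            gamma.accumulate(gdot.astype(_f32))
        if beta.requires_grad:
            beta.accumulate(gr.sum(axis=(0, 2)))
        if x.requires_grad:
            if training:
                gsum = gr.sum(axis=(0, 2)).reshape(shape)
                dx = a * (g - gsum * _f32(1.0 / m) -
                          xhat * (gdot.astype(_f32).reshape(shape) * _f32(1.0 / m)))
            else:
                dx = a * g
            x.accumulate(dx.astype(_f32, copy=False))

    return Tensor._make(out_data, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# classification losses
# ---------------------------------------------------------------------------

def softmax(x: np.ndarray | Tensor, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax on plain arrays (no tape)."""
    a = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
    a = a - a.max(axis=axis, keepdims=True)
    e = np.exp(a)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets against raw logits (fused with
    softmax for stability)."""
    logits = as_tensor(logits)
    targets = np.asarray(targets, dtype=np.int64)
    n = logits.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    loss = -logp[np.arange(n), targets].mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), targets] -= 1.0
            logits.accumulate((g * p / n).astype(_f32))

    return Tensor._make(np.asarray(loss, dtype=_f32), (logits,), backward)
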