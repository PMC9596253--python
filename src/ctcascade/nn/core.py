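"""Compact reverse-mode autodiff on numpy arrays.

Only the operations the segmentation and detection networks need are
implemented: 2-D convolution (via im2col and BLAS matmul), ReLU, 2x2 max
pooling, bilinear 2x upsampling, elementwise add, channel concatenation,
and the fused loss heads. Work happens in float32 by default (switchable
to float64 for gradient verification); convolution strides are always 1
(downsampling is done by pooling, as in the network design).
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

DEFAULT_DTYPE = np.dtype(np.float32)


@contextmanager
def default_dtype(dtype):
    """Temporarily switch the working precision (e.g. float64 when
    validating gradients against finite differences)."""
    global DEFAULT_DTYPE
    previous = DEFAULT_DTYPE
    DEFAULT_DTYPE = np.dtype(dtype)
    try:
        yield
    finally:
        DEFAULT_DTYPE = previous


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> np.ndarray:
        return self.data


def _result(data, parents, backward) -> Tensor:
    out = Tensor(data)
    needs = any(isinstance(p, Tensor) and (p.requires_grad or p._parents) for p in parents)
    if needs:
        out.requires_grad = True
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution

def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    # xp: (N, C, Hp, Wp) already padded -> (N, OH*OW, C*kh*kw)
    n, c, hp, wp = xp.shape
    oh, ow = hp - kh + 1, wp - kw + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return col.reshape(n, oh * ow, c * kh * kw), oh, ow


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, padding) -> Tensor:
    """2-D convolution, stride 1.

    padding: int (symmetric) or 4-tuple (top, bottom, left, right); the
    4-tuple form supports even kernels (2x2) that preserve spatial size.
    """
    if isinstance(padding, int):
        pt = pb = pl = pr = padding
    else:
        pt, pb, pl, pr = padding
    oc, ic, kh, kw = weight.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    col, oh, ow = _im2col(xp, kh, kw)
    wmat = weight.data.reshape(oc, ic * kh * kw)
    out = col @ wmat.T
    out += bias.data
    n = x.data.shape[0]
    out = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, oc, oh, ow)

    def backward(g):
        gm = g.reshape(n, oc, oh * ow).transpose(0, 2, 1)  # (N, OH*OW, OC)
        if bias.requires_grad:
            bias._accumulate(gm.sum(axis=(0, 1)))
        if weight.requires_grad:
            dw = np.einsum("nio,nik->ok", gm, col, optimize=True)
            weight._accumulate(dw.reshape(weight.shape))
        if x.requires_grad or x._parents:
            dcol = gm @ wmat  # (N, OH*OW, C*kh*kw)
            dcol = dcol.reshape(n, oh, ow, ic, kh, kw).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + oh, j:j + ow] += dcol[..., i, j]
            hp, wp = xp.shape[2], xp.shape[3]
            x._accumulate(dxp[:, :, pt:hp - pb or None, pl:wp - pr or None])

    return _result(out, (x, weight, bias), backward)


# ---------------------------------------------------------------------------
# pointwise / pooling / resampling

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def backward(g):
        x._accumulate(g * mask)

    return _result(out, (x,), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    blocks = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        db = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(db, idx[..., None], g[..., None], axis=-1)
        db = db.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(db.reshape(n, c, h, w))

    return _result(out, (x,), backward)


_INTERP_CACHE: dict[tuple, np.ndarray] = {}


def _upsample_matrix(n_in: int, dtype=None) -> np.ndarray:
    """Linear-interpolation 2x upsampling as a (2*n_in, n_in) matrix."""
    dtype = np.dtype(dtype or DEFAULT_DTYPE)
    key = (n_in, dtype)
    m = _INTERP_CACHE.get(key)
    if m is None:
        n_out = 2 * n_in
        src = (np.arange(n_out) + 0.5) / 2.0 - 0.5
        src = np.clip(src, 0, n_in - 1)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = (src - i0).astype(dtype)
        m = np.zeros((n_out, n_in), dtype=dtype)
        m[np.arange(n_out), i0] += 1.0 - w1
        m[np.arange(n_out), i1] += w1
        _INTERP_CACHE[key] = m
    return m


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2x spatial upsampling (separable linear interpolation)."""
    n, c, h, w = x.data.shape
    dt = x.data.dtype
    uh, uw = _upsample_matrix(h, dt), _upsample_matrix(w, dt)
    out = np.einsum("oh,nchw,pw->ncop", uh, x.data, uw, optimize=True)

    def backward(g):
        x._accumulate(np.einsum("oh,ncop,pw->nchw", uh, g, uw, optimize=True))

    return _result(out, (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g)
        if b.requires_grad or b._parents:
            b._accumulate(g)

    return _result(out, (a, b), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[1]
    out = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        if a.requires_grad or a._parents:
            a._accumulate(g[:, :ca])
        if b.requires_grad or b._parents:
            b._accumulate(g[:, ca:])

    return _result(out, (a, b), backward)


def slice_channels(x: Tensor, start: int, stop: int) -> Tensor:
    out = x.data[:, start:stop]

    def backward(g):
        full = np.zeros_like(x.data)
        full[:, start:stop] = g
        x._accumulate(full)

    return _result(out, (x,), backward)


def sigmoid_t(x: Tensor) -> Tensor:
    s = sigmoid(x.data)

    def backward(g):
        x._accumulate(g * s * (1.0 - s))

    return _result(s, (x,), backward)


# ---------------------------------------------------------------------------
# loss heads (fused: return scalar tensors)

def log_softmax_channels(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=1, keepdims=True))


def softmax_cross_entropy(logits: Tensor, target: np.ndarray,
                          class_weights: np.ndarray | None = None,
                          pixel_weights: np.ndarray | None = None) -> Tensor:
    """Weighted mean per-pixel cross-entropy between softmax(logits) and an
    integer class-index target. logits: (N, K, H, W); target: (N, H, W);
    pixel_weights (optional, same shape as target) down-weights or masks
    pixels, e.g. padding introduced to batch unevenly sized crops."""
    n, k, h, w = logits.data.shape
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= k:
        raise ValueError("target class index out of range")
    logp = log_softmax_channels(logits.data)
    onehot_ll = np.take_along_axis(logp, target[:, None, :, :], axis=1)[:, 0]
    if class_weights is not None or pixel_weights is not None:
        cw = np.ones(target.shape, dtype=logits.data.dtype)
        if class_weights is not None:
            cw *= np.asarray(class_weights, dtype=cw.dtype)[target]
        if pixel_weights is not None:
            cw *= np.asarray(pixel_weights, dtype=cw.dtype)
        denom = max(float(cw.sum()), 1e-12)
        loss = -(cw * onehot_ll).sum() / denom
    else:
        cw = None
        denom = float(n * h * w)
        loss = -onehot_ll.sum() / denom

    def backward(g):
        p = np.exp(logp)
        grad = p.copy()
        idx = target[:, None, :, :]
        np.put_along_axis(grad, idx, np.take_along_axis(grad, idx, axis=1) - 1.0, axis=1)
        if cw is not None:
            grad *= cw[:, None, :, :]
        logits._accumulate(grad * (g / denom))

    return _result(np.asarray(loss, dtype=logits.data.dtype), (logits,), backward)


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def bce_with_logits(logits: Tensor, target: np.ndarray,
                    pos_weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy on logits, numerically stable form.

    ``pos_weight`` multiplies the positive-target term, compensating for
    targets where positives are rare (e.g. objectness grids in which only
    the cells holding a box center are positive)."""
    z, t = logits.data, np.asarray(target, dtype=logits.data.dtype)
    base = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    if pos_weight != 1.0:
        # -[pw*t*log(s) + (1-t)*log(1-s)] = base + (pw-1)*t*(-log s)
        neg_log_s = np.maximum(-z, 0) + np.log1p(np.exp(-np.abs(z)))
        loss = base + (pos_weight - 1.0) * t * neg_log_s
    else:
        loss = base
    n = z.size

    def backward(g):
        s = sigmoid(z)
        grad = s * (1.0 + (pos_weight - 1.0) * t) - pos_weight * t
        logits._accumulate(grad * (g / n))

    return _result(np.asarray(loss.sum() / n, dtype=z.dtype), (logits,), backward)


def masked_l2(pred: Tensor, target: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over entries where mask is true (e.g. box
    regression restricted to positive detector cells)."""
    m = np.asarray(mask, dtype=pred.data.dtype)
    diff = (pred.data - np.asarray(target, dtype=pred.data.dtype)) * m
    denom = max(float(m.sum()), 1.0)
    loss = np.asarray((diff ** 2).sum() / denom, dtype=pred.data.dtype)

    def backward(g):
        pred._accumulate(diff * (2.0 * g / denom))

    return _result(loss, (pred,), backward)


def add_scalars(terms: list[Tensor], weights: list[float]) -> Tensor:
    out = np.asarray(sum(float(w) * float(t.data) for t, w in zip(terms, weights)),
                     dtype=terms[0].data.dtype)

    def backward(g):
        for t, w in zip(terms, weights):
            t._accumulate(w * g)

    return _result(out, tuple(terms), backward)
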