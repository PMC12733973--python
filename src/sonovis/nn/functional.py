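"""Composite and convolutional operations built on the autodiff ``Tensor``."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, pad2d

__all__ = [
    "softmax", "log_softmax", "cross_entropy", "layer_norm", "l2_normalize",
    "conv2d", "conv_transpose2d", "kl_divergence",
]


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.max_detached(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.max_detached(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``logits`` (N, K)."""
    logp = log_softmax(logits, axis=-1)
    n = logits.shape[0]
    picked = logp[np.arange(n), np.asarray(labels, dtype=int)]
    return -picked.mean()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise over the last axis, then scale and shift."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / (var + eps).sqrt() * gamma + beta


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + eps).sqrt()
    if float(norm.data.min()) < 1e-6:
        raise ValueError("cannot L2-normalize a (near-)zero vector")
    return x / norm


def kl_divergence(p: Tensor, q: Tensor, eps: float = 1e-12) -> Tensor:
    """KL(p || q) for two flat probability vectors/batches summed over last axis."""
    return (p * ((p + eps).log() - (q + eps).log())).sum(axis=-1)


# ---------------------------------------------------------------------------
# convolutions (NCHW layout)
# ---------------------------------------------------------------------------

def _cols_view(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """Strided (B, C, kh, kw, Ho, Wo) view of an already padded array."""
    b, c, h, w = x.shape
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    sb, sc, sy, sx = x.strides
    return np.lib.stride_tricks.as_strided(
        x, (b, c, kh, kw, ho, wo), (sb, sc, sy, sx, sy * sh, sx * sw), writeable=False
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int | tuple = 1, padding: int | tuple = 0) -> Tensor:
    """2-D cross-correlation: x (B,C,H,W) * w (O,C,kh,kw) -> (B,O,Ho,Wo)."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    ph, pw = (padding, padding) if isinstance(padding, int) else padding
    kh, kw = w.shape[-2:]
    xp = pad2d(x, ph, pw) if (ph or pw) else x
    cols = _cols_view(xp.data, kh, kw, sh, sw)
    out_data = np.einsum("bcpqij,ocpq->boij", cols, w.data, optimize=True)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    ho, wo = out_data.shape[-2:]

    def backward(g):
        if w.requires_grad:
            gw = np.einsum("boij,bcpqij->ocpq", g, cols, optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            gx = np.zeros_like(xp.data)
            t = np.einsum("boij,ocpq->bcpqij", g, w.data, optimize=True)
            for p in range(kh):
                for q in range(kw):
                    gx[:, :, p:p + ho * sh:sh, q:q + wo * sw:sw] += t[:, :, p, q]
            xp._accum(gx)

    prev = (xp, w) if b is None else (xp, w, b)
    return x._make(out_data, prev, backward)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2, padding: int = 1,
                     output_padding: int = 0) -> Tensor:
    """Transposed 2-D convolution: x (B,C,H,W), w (C,O,kh,kw).

    Output spatial size: (H-1)*stride - 2*padding + kh + output_padding.
    """
    bsz, cin, h, wdt = x.shape
    _, cout, kh, kw = w.shape
    s, p, op = stride, padding, output_padding
    ho = (h - 1) * s - 2 * p + kh + op
    wo = (wdt - 1) * s - 2 * p + kw + op
    # scatter forward into a padded canvas, then crop
    full = np.zeros((bsz, cout, ho + 2 * p, wo + 2 * p), dtype=x.dtype)
    t = np.einsum("bcij,copq->bopqij", x.data, w.data, optimize=True)
    for pp in range(kh):
        for qq in range(kw):
            full[:, :, pp:pp + h * s:s, qq:qq + wdt * s:s] += t[:, :, pp, qq]
    out_data = full[:, :, p:p + ho, p:p + wo] if p else full[:, :, :ho, :wo]
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    def backward(g):
        gfull = np.zeros((bsz, cout, ho + 2 * p, wo + 2 * p), dtype=g.dtype)
        if p:
            gfull[:, :, p:p + ho, p:p + wo] = g
        else:
            gfull[:, :, :ho, :wo] = g
        cols = _cols_view(gfull, kh, kw, s, s)  # (B, O, kh, kw, H, W)
        if x.requires_grad:
            gx = np.einsum("bopqij,copq->bcij", cols[:, :, :, :, :h, :wdt], w.data,
                           optimize=True)
            x._accum(gx)
        if w.requires_grad:
            gw = np.einsum("bopqij,bcij->copq", cols[:, :, :, :, :h, :wdt], x.data,
                           optimize=True)
            w._accum(gw)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    prev = (x, w) if b is None else (x, w, b)
    return x._make(out_data, prev, backward)


def resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """1-D bilinear interpolation matrix (n_out, n_in), edge-clamped.

    Output coordinate i samples input coordinate (i + 0.5) * n_in / n_out - 0.5.
    """
    w = np.zeros((n_out, n_in))
    for i in range(n_out):
        x = (i + 0.5) * n_in / n_out - 0.5
        x0 = int(np.floor(x))
        f = x - x0
        x0c = min(max(x0, 0), n_in - 1)
        x1c = min(max(x0 + 1, 0), n_in - 1)
        w[i, x0c] += 1.0 - f
        w[i, x1c] += f
    return w


def resize_bilinear(x: Tensor, out_hw: tuple) -> Tensor:
    """Differentiable bilinear resize of the last two axes of ``x``.

    Implemented as two interpolation-matrix products, so gradients flow
    through the resize (the attention marginal and saliency maps need this).
    """
    h_out, w_out = out_hw
    ry = Tensor(resize_matrix(h_out, x.shape[-2]).astype(x.dtype))
    rx = Tensor(resize_matrix(w_out, x.shape[-1]).astype(x.dtype))
    swap = tuple(range(x.ndim - 2)) + (x.ndim - 1, x.ndim - 2)
    out = x.transpose(swap) @ ry.transpose((1, 0))   # interpolate rows
    return out.transpose(swap) @ rx.transpose((1, 0))  # then columns
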