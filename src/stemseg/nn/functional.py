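"""Array-level neural-network operators.

Convolutions run as im2col + GEMM; the deformable convolution gathers its
taps with bilinear interpolation at learned fractional positions, with
off-canvas samples contributing zero.  All functions take and return
:class:`~stemseg.nn.tensor.Tensor` in NCHW layout.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "conv2d",
    "deform_conv2d",
    "max_pool2d",
    "global_avg_pool",
    "global_max_pool",
    "upsample_bilinear",
]


def _out_size(size: int, k: int, stride: int, pad: int, dilation: int) -> int:
    eff = dilation * (k - 1) + 1
    return (size + 2 * pad - eff) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dilation: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C, kh, kw, OH, OW) patch view (copied)."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = _out_size(h, kh, stride, pad, dilation)
    ow = _out_size(w, kw, stride, pad, dilation)
    sn, sc, sh, sw = x.strides
    shape = (n, c, kh, kw, oh, ow)
    strides = (sn, sc, sh * dilation, sw * dilation, sh * stride, sw * stride)
    return np.ascontiguousarray(
        np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    )


def _col2im(
    cols: np.ndarray,
    x_shape: tuple[int, ...],
    stride: int,
    pad: int,
    dilation: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to the image."""
    n, c, h, w = x_shape
    _, _, kh, kw, oh, ow = cols.shape
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(kh):
        hi = i * dilation
        for j in range(kw):
            wj = j * dilation
            gx[:, :, hi : hi + stride * oh : stride, wj : wj + stride * ow : stride] += cols[
                :, :, i, j
            ]
    if pad:
        gx = gx[:, :, pad : pad + h, pad : pad + w]
    return gx


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """2-D convolution (cross-correlation), NCHW, square stride/pad/dilation."""
    n, c, h, w = x.shape
    f, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {cw}")
    cols = _im2col(x.data, kh, kw, stride, padding, dilation)  # (N,C,kh,kw,OH,OW)
    oh, ow = cols.shape[4], cols.shape[5]
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    wf = weight.data.reshape(f, c * kh * kw)
    out = np.einsum("fk,nkl->nfl", wf, cols2, optimize=True).reshape(n, f, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, f, 1, 1)

    def backward(g):
        gl = g.reshape(n, f, oh * ow)
        gw = np.einsum("nfl,nkl->fk", gl, cols2, optimize=True).reshape(weight.shape)
        gcols = np.einsum("fk,nfl->nkl", wf, gl, optimize=True).reshape(
            n, c, kh, kw, oh, ow
        )
        gx = _col2im(gcols, x.shape, stride, padding, dilation)
        gb = None if bias is None else g.sum(axis=(0, 2, 3))
        return (gx, gw, gb) if bias is not None else (gx, gw)

    parents = (x, weight, bias) if bias is not None else (x, weight)
    return Tensor._make(out, parents, backward)


def deform_conv2d(
    x: Tensor,
    weight: Tensor,
    offsets: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    dilation: int = 1,
) -> Tensor:
    """Deformable 2-D convolution (offset-only variant).

    Each kernel tap samples the input at its regular grid position displaced
    by a learned per-output-location offset, evaluated by bilinear
    interpolation; positions outside the canvas contribute zero.  ``offsets``
    has shape (N, 2*kh*kw, OH, OW) with channels ordered
    (dy_0, dx_0, dy_1, dx_1, ...) over row-major kernel taps.
    """
    n, c, h, w = x.shape
    f, cw, kh, kw = weight.shape
    if cw != c:
        raise ValueError(f"channel mismatch: input has {c}, weight expects {cw}")
    k = kh * kw
    oh = _out_size(h, kh, stride, padding, dilation)
    ow = _out_size(w, kw, stride, padding, dilation)
    if offsets.shape != (n, 2 * k, oh, ow):
        raise ValueError(
            f"offset shape {offsets.shape} incompatible with kernel {kh}x{kw} "
            f"and output {(n, 2 * k, oh, ow)}"
        )
    off = offsets.data.reshape(n, k, 2, oh, ow)
    ki, kj = np.divmod(np.arange(k), kw)
    base_y = (
        -padding
        + stride * np.arange(oh)[None, :, None]
        + dilation * ki[:, None, None]
    )  # (K, OH, 1)
    base_x = (
        -padding
        + stride * np.arange(ow)[None, None, :]
        + dilation * kj[:, None, None]
    )  # (K, 1, OW)
    py = base_y + off[:, :, 0]  # (N, K, OH, OW)
    px = base_x + off[:, :, 1]

    y0 = np.floor(py).astype(np.int64)
    x0 = np.floor(px).astype(np.int64)
    wy = (py - y0).astype(x.dtype)
    wx = (px - x0).astype(x.dtype)

    xf = x.data.reshape(n, c, h * w)
    nn = np.arange(n)[:, None, None, None]

    def corner(yy, xx):
        valid = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
        idx = np.where(valid, yy * w + xx, 0)
        vals = xf[nn, :, idx]  # (N, K, OH, OW, C)
        vals = np.moveaxis(vals, -1, 1)  # (N, C, K, OH, OW)
        return vals * valid[:, None], valid, idx

    v00, m00, i00 = corner(y0, x0)
    v01, m01, i01 = corner(y0, x0 + 1)
    v10, m10, i10 = corner(y0 + 1, x0)
    v11, m11, i11 = corner(y0 + 1, x0 + 1)

    w00 = (1 - wy) * (1 - wx)
    w01 = (1 - wy) * wx
    w10 = wy * (1 - wx)
    w11 = wy * wx
    sampled = (
        v00 * w00[:, None]
        + v01 * w01[:, None]
        + v10 * w10[:, None]
        + v11 * w11[:, None]
    )  # (N, C, K, OH, OW)

    scol = sampled.reshape(n, c * k, oh * ow)
    wf = weight.data.reshape(f, c * k)
    out = np.einsum("fk,nkl->nfl", wf, scol, optimize=True).reshape(n, f, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, f, 1, 1)

    def backward(g):
        gl = g.reshape(n, f, oh * ow)
        gw = np.einsum("nfl,nkl->fk", gl, scol, optimize=True).reshape(weight.shape)
        gs = np.einsum("fk,nfl->nkl", wf, gl, optimize=True).reshape(n, c, k, oh, ow)

        # scatter-add via bincount on flattened (n, c, pixel) indices
        hw = h * w
        plane = (np.arange(n * c, dtype=np.int64) * hw).reshape(n, c, 1, 1, 1)
        flat_idx = []
        flat_val = []
        for vmask, vidx, vw in (
            (m00, i00, w00),
            (m01, i01, w01),
            (m10, i10, w10),
            (m11, i11, w11),
        ):
            contrib = gs * (vw * vmask)[:, None]
            flat_idx.append((plane + vidx[:, None]).ravel())
            flat_val.append(contrib.ravel())
        gx = np.bincount(
            np.concatenate(flat_idx), weights=np.concatenate(flat_val), minlength=n * c * hw
        ).astype(x.dtype).reshape(x.shape)

        # d(sample)/d(py) and /d(px) from the bilinear weights
        dpy = (
            ((v10 - v00) * (1 - wx)[:, None] + (v11 - v01) * wx[:, None]) * gs
        ).sum(axis=1)
        dpx = (
            ((v01 - v00) * (1 - wy)[:, None] + (v11 - v10) * wy[:, None]) * gs
        ).sum(axis=1)
        goff = np.stack([dpy, dpx], axis=2).reshape(offsets.shape)

        gb = None if bias is None else g.sum(axis=(0, 2, 3))
        return (gx, gw, goff, gb) if bias is not None else (gx, gw, goff)

    parents = (x, weight, offsets, bias) if bias is not None else (x, weight, offsets)
    return Tensor._make(out, parents, backward)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    xp = x.data
    if padding:
        xp = np.pad(
            xp,
            ((0, 0), (0, 0), (padding, padding), (padding, padding)),
            constant_values=-np.inf,
        )
    cols = _im2col(xp, kernel, kernel, stride, 0, 1)  # (N,C,k,k,OH,OW)
    n_, c_, _, _, oh, ow = cols.shape
    flat = cols.reshape(n_, c_, kernel * kernel, oh, ow)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, arg[:, :, None], g[:, :, None], axis=2)
        gxp = _col2im(gcols.reshape(cols.shape), (n, c, h + 2 * padding, w + 2 * padding), stride, 0, 1)
        if padding:
            gxp = gxp[:, :, padding : padding + h, padding : padding + w]
        return (gxp,)

    return Tensor._make(out, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3), keepdims=True)


def global_max_pool(x: Tensor) -> Tensor:
    return x.max(axis=(2, 3), keepdims=True)


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """1-D bilinear resampling matrix, half-pixel (align_corners=False) convention."""
    a = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    a[np.arange(n_out), lo] += 1.0 - frac
    a[np.arange(n_out), hi] += frac
    return a


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize to ``size`` as two separable 1-D linear maps."""
    _, _, h, w = x.shape
    oh, ow = size
    a = _interp_matrix(h, oh, x.dtype)
    b = _interp_matrix(w, ow, x.dtype)
    out = np.einsum("ij,ncjk,lk->ncil", a, x.data, b, optimize=True)

    def backward(g):
        return (np.einsum("ij,ncil,lk->ncjk", a, g, b, optimize=True),)

    return Tensor._make(out, (x,), backward)
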