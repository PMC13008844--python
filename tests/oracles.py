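"""Independent brute-force reference implementations used by the tests.

Everything here is written as plain numpy loops, deliberately ignoring the
vectorized implementations under test.
"""

import numpy as np
from scipy.special import expit


def naive_conv2d(x, w, b=None, stride=1, padding=0, dilation=1):
    """Direct sampling-loop convolution, NCHW."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    eff_h, eff_w = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
    oh = (h + 2 * padding - eff_h) // stride + 1
    ow = (wd + 2 * padding - eff_w) // stride + 1
    out = np.zeros((n, f, oh, ow), dtype=float)
    for ni in range(n):
        for fi in range(f):
            for oy in range(oh):
                for ox in range(ow):
                    acc = 0.0
                    for ci in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                y = oy * stride - padding + i * dilation
                                xx = ox * stride - padding + j * dilation
                                if 0 <= y < h and 0 <= xx < wd:
                                    acc += w[fi, ci, i, j] * x[ni, ci, y, xx]
                    out[ni, fi, oy, ox] = acc + (b[fi] if b is not None else 0.0)
    return out


def bilinear_at(plane, y, x):
    """Zero-padded bilinear sample of a 2-D array at a fractional point."""
    h, w = plane.shape
    y0, x0 = int(np.floor(y)), int(np.floor(x))
    val = 0.0
    for dy, wy in ((0, 1 - (y - y0)), (1, y - y0)):
        for dx, wx in ((0, 1 - (x - x0)), (1, x - x0)):
            yy, xx = y0 + dy, x0 + dx
            if 0 <= yy < h and 0 <= xx < w:
                val += wy * wx * plane[yy, xx]
    return val


def naive_deform_conv2d(x, w, offsets, b=None, stride=1, padding=0, dilation=1):
    """Per-position bilinear-gather loop for the deformable convolution."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    k = kh * kw
    oh, ow = offsets.shape[2], offsets.shape[3]
    out = np.zeros((n, f, oh, ow), dtype=float)
    for ni in range(n):
        for oy in range(oh):
            for ox in range(ow):
                sampled = np.zeros((c, k))
                for t in range(k):
                    i, j = divmod(t, kw)
                    py = oy * stride - padding + i * dilation + offsets[ni, 2 * t, oy, ox]
                    px = ox * stride - padding + j * dilation + offsets[ni, 2 * t + 1, oy, ox]
                    for ci in range(c):
                        sampled[ci, t] = bilinear_at(x[ni, ci], py, px)
                for fi in range(f):
                    out[ni, fi, oy, ox] = np.sum(w[fi].reshape(c, k) * sampled) + (
                        b[fi] if b is not None else 0.0
                    )
    return out


def naive_cbam(x, fc1_w, fc1_b, fc2_w, fc2_b, conv_w, conv_b):
    """Elementwise re-implementation of channel-then-spatial attention.

    fc* are the shared-MLP weights (in-features x out-features); conv_* the
    7x7 spatial-attention filter over [channel-avg; channel-max].
    """
    c, h, w = x.shape

    def mlp(v):
        return np.maximum(v @ fc1_w + fc1_b, 0.0) @ fc2_w + fc2_b

    mc = expit(mlp(x.mean(axis=(1, 2))) + mlp(x.max(axis=(1, 2))))
    f1 = mc[:, None, None] * x
    pooled = np.stack([f1.mean(axis=0), f1.max(axis=0)])
    k = conv_w.shape[-1]
    pad = k // 2
    ms = np.zeros((h, w))
    for y in range(h):
        for xx in range(w):
            acc = conv_b[0]
            for ci in range(2):
                for i in range(k):
                    for j in range(k):
                        yy, xj = y - pad + i, xx - pad + j
                        if 0 <= yy < h and 0 <= xj < w:
                            acc += conv_w[0, ci, i, j] * pooled[ci, yy, xj]
            ms[y, xx] = expit(acc)
    return ms[None] * f1, mc, ms


def naive_msaa(x, block):
    """Step-by-step evaluation of the MSAA equations with the block's own
    weights, using the naive convolution above."""
    xb = x[None]

    def conv(mod, inp):
        b = None if mod.bias is None else mod.bias.data.astype(float)
        return naive_conv2d(inp, mod.weight.data.astype(float), b, mod.stride, mod.padding, mod.dilation)

    z = conv(block.reduce, xb)
    u = conv(block.conv3, z) + conv(block.conv5, z) + conv(block.conv7, z)
    pooled = np.concatenate([u.mean(axis=1, keepdims=True), u.max(axis=1, keepdims=True)], axis=1)
    ws = expit(conv(block.spatial_gate.conv, pooled))

    def mlp_vec(v, gate):
        h1 = np.maximum(v @ gate.fc1.weight.data + gate.fc1.bias.data, 0.0)
        return h1 @ gate.fc2.weight.data + gate.fc2.bias.data

    gav = u.mean(axis=(2, 3))
    gmx = u.max(axis=(2, 3))
    wc = expit(mlp_vec(gav, block.channel_gate) + mlp_vec(gmx, block.channel_gate))[:, :, None, None]
    us = ws * z
    uc = wc * z
    return (conv(block.project, us * uc) + xb)[0], ws[0], wc[0]


def winding_number_inside(px, py, polygon):
    """Scalar nonzero-winding point-in-polygon test."""
    wn = 0
    pts = list(polygon)
    for (x1, y1), (x2, y2) in zip(pts, pts[1:] + pts[:1]):
        is_left = (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1)
        if y1 <= py < y2 and is_left > 0:
            wn += 1
        elif y2 <= py < y1 and is_left < 0:
            wn -= 1
    return wn != 0
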