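"""Attention and context blocks: CBAM, MSAA, and the four-rate C-ASPP.

CBAM applies channel attention then spatial attention as multiplicative
recalibration maps in (0,1):

    Mc = sigmoid(MLP(avgpool F) + MLP(maxpool F)),   F'  = Mc (x) F
    Ms = sigmoid(conv7x7([mean_c F'; max_c F'])),    F'' = Ms (x) F'

MSAA refines a skip feature N (C,H,W): a 1x1 convolution reduces channels to
D, parallel 3/5/7 convolutions aggregate multi-scale context U, spatial and
channel attention maps modulate the reduced feature (Us = Ws . Z,
Uc = Wc . Z), and their interaction product is projected back and added
residually: K = conv1x1(Us . Uc) + N.

C-ASPP runs a 1x1 branch, one 3x3 atrous branch per dilation rate (each
followed by CBAM), and a global-pooling branch, then fuses the concatenation
with a 1x1 projection; spatial size is preserved throughout.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import Tensor
from .config import GriddingError, ModelConfig, validate_dilation_set

__all__ = ["ChannelAttention", "SpatialAttention", "CBAM", "MSAA", "CASPP", "cbam", "msaa", "c_aspp"]


class ChannelAttention(nn.Module):
    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def _mlp(self, pooled: Tensor) -> Tensor:
        n, c = pooled.shape[0], pooled.shape[1]
        flat = pooled.reshape(n, c)
        return self.fc2(self.fc1(flat).relu())

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        logits = self._mlp(nn.global_avg_pool(x)) + self._mlp(nn.global_max_pool(x))
        return logits.sigmoid().reshape(n, c, 1, 1)


class SpatialAttention(nn.Module):
    def __init__(self, kernel: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, padding=kernel // 2)

    def forward(self, x: Tensor) -> Tensor:
        pooled = nn.concat([x.mean(axis=1, keepdims=True), x.max(axis=1, keepdims=True)], axis=1)
        return self.conv(pooled).sigmoid()


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention."""

    def __init__(self, channels: int, reduction: int = 16):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction)
        self.spatial = SpatialAttention()

    def forward(self, x: Tensor) -> Tensor:
        x = self.channel(x) * x
        return self.spatial(x) * x


def cbam(x: Tensor | np.ndarray, reduction: int = 16, module: CBAM | None = None) -> Tensor:
    """Apply CBAM to a C x H x W or N x C x H x W feature map.

    Builds a freshly initialized block unless ``module`` is given (tests pass
    a block with known weights)."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape(1, *t.shape)
    block = module if module is not None else CBAM(t.shape[1], reduction)
    out = block(t)
    return out.reshape(*out.shape[1:]) if squeeze else out


class MSAA(nn.Module):
    """Multi-scale attention aggregation for skip-connection features.

    The spatial weight map Ws (1,H,W) and channel weight vector Wc (D,1,1)
    are derived from the aggregated multi-scale feature U with the CBAM
    idiom: Ws from a 7x7 convolution over channel-pooled U, Wc from an MLP
    over globally pooled U.  Both lie in (0,1).
    """

    def __init__(self, channels: int, reduction: int | None = None):
        super().__init__()
        d = reduction if reduction is not None else max(channels // 4, 8)
        d = min(channels, max(int(d), 1))
        self.d = d
        self.reduce = nn.Conv2d(channels, d, 1)
        self.conv3 = nn.Conv2d(d, d, 3, padding=1)
        self.conv5 = nn.Conv2d(d, d, 5, padding=2)
        self.conv7 = nn.Conv2d(d, d, 7, padding=3)
        self.spatial_gate = SpatialAttention()
        self.channel_gate = ChannelAttention(d, reduction=4)
        self.project = nn.Conv2d(d, channels, 1)

    def forward(self, x: Tensor) -> Tensor:
        z = self.reduce(x)
        u = self.conv3(z) + self.conv5(z) + self.conv7(z)
        ws = self.spatial_gate(u)          # (N,1,H,W)
        wc = self.channel_gate(u)          # (N,D,1,1)
        us = ws * z
        uc = wc * z
        return self.project(us * uc) + x


def msaa(x: Tensor | np.ndarray, reduction: int | None = None, module: MSAA | None = None) -> Tensor:
    """Apply MSAA to a C x H x W or N x C x H x W feature map."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape(1, *t.shape)
    block = module if module is not None else MSAA(t.shape[1], reduction)
    out = block(t)
    return out.reshape(*out.shape[1:]) if squeeze else out


class _ConvBnRelu(nn.Module):
    def __init__(self, cin: int, cout: int, k: int, dilation: int = 1):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, padding=(k // 2) * dilation, dilation=dilation, bias=False)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).relu()


class _AsppBranch(nn.Module):
    def __init__(self, cin: int, cout: int, rate: int, use_cbam: bool, cbam_reduction: int):
        super().__init__()
        self.rate = rate
        self.body = _ConvBnRelu(cin, cout, 3, dilation=rate)
        self.cbam = CBAM(cout, cbam_reduction) if use_cbam else None

    def forward(self, x: Tensor) -> Tensor:
        out = self.body(x)
        return self.cbam(out) if self.cbam is not None else out


class _ImagePoolBranch(nn.Module):
    def __init__(self, cin: int, cout: int, use_cbam: bool, cbam_reduction: int):
        super().__init__()
        self.proj = _ConvBnRelu(cin, cout, 1)
        self.cbam = CBAM(cout, cbam_reduction) if use_cbam else None

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        pooled = self.proj(nn.global_avg_pool(x))
        if self.cbam is not None:
            pooled = self.cbam(pooled)
        # broadcast the 1x1 context vector back over the spatial grid
        return pooled * Tensor(np.ones((1, 1, h, w), dtype=pooled.dtype))


class CASPP(nn.Module):
    """Four-rate atrous pyramid with per-branch CBAM over the deepest
    encoder feature.  Branches: 1x1 conv, one 3x3 atrous conv per rate
    (CBAM-refined), and a global-average-pooling image branch."""

    def __init__(self, cin: int, cout: int, config: ModelConfig):
        super().__init__()
        rates = config.aspp_rates
        if config.strict_rates:
            g, ok = validate_dilation_set(rates)
            if not ok:
                raise GriddingError(f"dilation rates {rates.rates} share common factor {g}")
        self.point = _ConvBnRelu(cin, cout, 1)
        self.atrous = [
            _AsppBranch(cin, cout, r, config.cbam_on_branches, config.cbam_reduction)
            for r in rates.rates
        ]
        for i, branch in enumerate(self.atrous):
            setattr(self, f"atrous{i}", branch)
        self.image_pool = _ImagePoolBranch(cin, cout, config.cbam_on_image_pool, config.cbam_reduction)
        self.project = _ConvBnRelu(cout * (len(self.atrous) + 2), cout, 1)

    @property
    def branches(self) -> list[nn.Module]:
        return [self.point, *self.atrous, self.image_pool]

    def forward(self, x: Tensor) -> Tensor:
        outs = [branch(x) for branch in self.branches]
        return self.project(nn.concat(outs, axis=1))


def c_aspp(x: Tensor | np.ndarray, config: ModelConfig | None = None, module: CASPP | None = None) -> Tensor:
    """Apply C-ASPP to a C x H x W or N x C x H x W feature map."""
    cfg = config if config is not None else ModelConfig()
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape(1, *t.shape)
    block = module if module is not None else CASPP(t.shape[1], cfg.scaled(cfg.aspp_channels), cfg)
    out = block(t)
    return out.reshape(*out.shape[1:]) if squeeze else out
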