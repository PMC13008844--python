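"""RAM-UNet: deformable-ResNet50 encoder, C-ASPP context block, and a
progressive-fusion decoder with MSAA-refined skip connections.

Decoder wiring: starting from the context feature at stride 32, each level
bilinearly upsamples by 2, refines the corresponding encoder skip feature
with MSAA, concatenates, and smooths with a 3x3 convolution; a final 1x1
classifier and bilinear upsample restore the input resolution.  Prediction
is the per-pixel argmax over the two class scores, with ties resolved to
background.
"""

from __future__ import annotations

import numpy as np

from .. import nn
from ..nn import Tensor
from .blocks import CASPP, MSAA, _ConvBnRelu
from .config import ModelConfig
from .resnet import ResNetEncoder

__all__ = ["RamUnet", "ram_unet_forward"]


class _FusionLevel(nn.Module):
    def __init__(self, cin_up: int, cin_skip: int, cout: int, cfg: ModelConfig):
        super().__init__()
        self.msaa = MSAA(cin_skip, cfg.msaa_reduction) if cfg.msaa_on else None
        self.smooth = _ConvBnRelu(cin_up + cin_skip, cout, 3)

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = nn.upsample_bilinear(x, (skip.shape[2], skip.shape[3]))
        if self.msaa is not None:
            skip = self.msaa(skip)
        return self.smooth(nn.concat([x, skip], axis=1))


class RamUnet(nn.Module):
    def __init__(self, config: ModelConfig | None = None):
        super().__init__()
        cfg = config if config is not None else ModelConfig()
        self.config = cfg
        self.encoder = ResNetEncoder(cfg.scaled, cfg.deformable_stages)
        c1, c2, c3, c4 = self.encoder.stage_channels
        ctx = cfg.scaled(cfg.aspp_channels)
        if cfg.use_aspp:
            self.context = CASPP(c4, ctx, cfg)
        else:
            self.context = _ConvBnRelu(c4, ctx, 1)
        d1, d2, d3 = (cfg.scaled(c) for c in cfg.decoder_channels)
        self.fuse3 = _FusionLevel(ctx, c3, d1, cfg)
        self.fuse2 = _FusionLevel(d1, c2, d2, cfg)
        self.fuse1 = _FusionLevel(d2, c1, d3, cfg)
        self.classifier = nn.Conv2d(d3, cfg.num_classes, 1)

    def forward(self, x: Tensor) -> Tensor:
        """(N,3,H,W) image batch -> (N,num_classes,H,W) class scores."""
        n, c, h, w = x.shape
        if h % 32 or w % 32:
            raise ValueError(f"input spatial size must be divisible by 32, got {h}x{w}")
        f1, f2, f3, f4 = self.encoder(x)
        y = self.context(f4)
        y = self.fuse3(y, f3)
        y = self.fuse2(y, f2)
        y = self.fuse1(y, f1)
        y = self.classifier(y)
        return nn.upsample_bilinear(y, (h, w))

    # -- inference helpers ---------------------------------------------------

    def forward_np(self, image: np.ndarray) -> np.ndarray:
        """Score a single 3 x H x W float image without building a graph."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 3 or image.shape[0] != 3:
            raise ValueError(f"expected a 3xHxW image, got shape {image.shape}")
        with nn.no_grad():
            scores = self.forward(Tensor(image[None]))
        return scores.data[0]

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Binary stem mask for a 3 x H x W image (argmax; ties -> background)."""
        scores = self.forward_np(image)
        return (scores[1] > scores[0]).astype(np.uint8)


def ram_unet_forward(image: np.ndarray, config: ModelConfig | RamUnet) -> np.ndarray:
    """Per-class score map num_classes x H x W for a 3 x H x W image.

    ``config`` may be a built model (weights reused) or a ModelConfig, in
    which case a freshly initialized network is constructed.
    """
    model = config if isinstance(config, RamUnet) else RamUnet(config)
    return model.forward_np(image)
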