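"""ResNet50-style encoder whose bottleneck 3x3 convolutions can be swapped
for deformable convolutions per stage.

The deformable variant learns a per-position sampling offset for each kernel
tap from a parallel zero-initialized convolution branch, so a freshly built
deformable encoder computes exactly what its standard counterpart does and
then learns to bend its sampling grid along curved stem contours.
"""

from __future__ import annotations

from .. import nn
from ..nn import Tensor

__all__ = ["Bottleneck", "ResNetEncoder"]

_STAGE_BLOCKS = (3, 4, 6, 3)


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin: int, planes: int, stride: int = 1, deformable: bool = False):
        super().__init__()
        cout = planes * self.expansion
        self.conv1 = nn.Conv2d(cin, planes, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(planes)
        if deformable:
            self.conv2 = nn.DeformConv2d(planes, planes, 3, stride=stride, padding=1, bias=False)
        else:
            self.conv2 = nn.Conv2d(planes, planes, 3, stride=stride, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(planes)
        self.conv3 = nn.Conv2d(planes, cout, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(cout)
        self.downsample = None
        if stride != 1 or cin != cout:
            self.downsample = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False), nn.BatchNorm2d(cout)
            )

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        identity = self.downsample(x) if self.downsample is not None else x
        return (out + identity).relu()


class ResNetEncoder(nn.Module):
    """Stem + four stages at output strides 4, 8, 16 and 32.

    ``width_scale`` maps nominal channel counts (64, 128, ...) to actual
    ones; ``deformable_stages`` lists the 1-based stages whose bottlenecks
    use deformable 3x3 convolutions.
    """

    def __init__(self, width_scale, deformable_stages: tuple[int, ...] = ()):
        super().__init__()
        stem_out = width_scale(64)
        self.conv1 = nn.Conv2d(3, stem_out, 7, stride=2, padding=3, bias=False)
        self.bn1 = nn.BatchNorm2d(stem_out)
        self.stage_channels: list[int] = []
        cin = stem_out
        self.stages: list[nn.Sequential] = []
        for i, nblocks in enumerate(_STAGE_BLOCKS):
            planes = width_scale(64 * 2**i)
            stride = 1 if i == 0 else 2
            deform = (i + 1) in deformable_stages
            blocks = []
            for b in range(nblocks):
                blocks.append(
                    Bottleneck(cin, planes, stride=stride if b == 0 else 1, deformable=deform)
                )
                cin = planes * Bottleneck.expansion
            stage = nn.Sequential(*blocks)
            self.stages.append(stage)
            setattr(self, f"layer{i + 1}", stage)
            self.stage_channels.append(cin)

    def forward(self, x: Tensor) -> list[Tensor]:
        """Return the four stage outputs, shallowest (stride 4) first."""
        x = self.bn1(self.conv1(x)).relu()
        x = nn.max_pool2d(x, 3, 2, 1)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats
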