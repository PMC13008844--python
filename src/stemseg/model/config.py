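"""Model configuration: dilation-set design rules and the network's ablation
switches.

Thin, curved stems are easily lost by dilated-convolution pyramids whose
rates share a common factor: the stacked kernels then sample a sparse
lattice and leave periodic blind spots on continuous structures (the
"gridding effect").  A rate set is therefore admitted only when
gcd(r1, ..., rn) = 1.  The default pyramid (1, 2, 7, 15) spans receptive
fields from 3x3 up to 31x31 for a 3x3 kernel, covering stem edges, branch
junctions and whole-plant layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from functools import reduce

__all__ = [
    "DilationSet",
    "ModelConfig",
    "GriddingError",
    "effective_receptive_field",
    "validate_dilation_set",
]


class GriddingError(ValueError):
    """Raised when a dilation set with a common factor > 1 is used in strict mode."""


def effective_receptive_field(k: int, r: int) -> int:
    """Effective kernel extent of a k x k convolution at dilation rate r:
    k_d = k + (k-1)(r-1).  ``k`` must be odd and positive, ``r`` positive."""
    if k < 1 or r < 1:
        raise ValueError(f"kernel and rate must be positive, got k={k}, r={r}")
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got k={k}")
    return k + (k - 1) * (r - 1)


@dataclass(frozen=True)
class DilationSet:
    """An ordered set of dilation rates for a shared kernel size."""

    rates: tuple[int, ...] = (1, 2, 7, 15)
    kernel: int = 3

    def __post_init__(self):
        rates = tuple(int(r) for r in self.rates)
        object.__setattr__(self, "rates", rates)
        if len(rates) < 1:
            raise ValueError("dilation set must contain at least one rate")
        if any(r < 1 for r in rates):
            raise ValueError(f"rates must be positive: {rates}")
        if any(a >= b for a, b in zip(rates, rates[1:])):
            raise ValueError(f"rates must be strictly increasing: {rates}")

    def receptive_fields(self) -> tuple[int, ...]:
        return tuple(effective_receptive_field(self.kernel, r) for r in self.rates)


def validate_dilation_set(rates: DilationSet | tuple[int, ...]) -> tuple[int, bool]:
    """Greatest common divisor of the rates and whether the set is
    gridding-free (gcd == 1)."""
    if isinstance(rates, DilationSet):
        rates = rates.rates
    rates = tuple(rates)
    if not rates:
        raise ValueError("empty dilation set")
    g = reduce(math.gcd, rates)
    return g, g == 1


@dataclass
class ModelConfig:
    """Architecture switches for RAM-UNet and its ablations.

    width_mult scales every channel count (1.0 is the full network; tests use
    1/8).  deformable_stages selects which of the four encoder stages replace
    the bottleneck 3x3 convolution with its deformable variant; an empty set
    restores a plain ResNet50.  cbam_on_branches attaches CBAM to each atrous
    branch of the context block; msaa_on enables skip-feature refinement in
    the decoder.  strict_rates rejects dilation sets failing the gcd
    criterion at build time.
    """

    num_classes: int = 2
    width_mult: float = 1.0
    deformable_stages: tuple[int, ...] = (1, 2, 3, 4)
    aspp_rates: DilationSet = field(default_factory=DilationSet)
    use_aspp: bool = True
    aspp_channels: int = 256
    cbam_on_branches: bool = True
    cbam_on_image_pool: bool = False
    cbam_reduction: int = 16
    msaa_on: bool = True
    msaa_reduction: int | None = None
    decoder_channels: tuple[int, ...] = (256, 128, 64)
    strict_rates: bool = True

    def __post_init__(self):
        self.deformable_stages = tuple(sorted(set(int(s) for s in self.deformable_stages)))
        if any(s not in (1, 2, 3, 4) for s in self.deformable_stages):
            raise ValueError(f"deformable stages must be within 1..4: {self.deformable_stages}")
        if isinstance(self.aspp_rates, (tuple, list)):
            self.aspp_rates = DilationSet(tuple(self.aspp_rates))
        if len(self.decoder_channels) != 3:
            raise ValueError("decoder_channels must list the three fusion widths")
        if self.strict_rates and self.use_aspp:
            g, ok = validate_dilation_set(self.aspp_rates)
            if not ok:
                raise GriddingError(
                    f"dilation rates {self.aspp_rates.rates} share a common factor "
                    f"{g}; the pyramid would sample a sparse grid (gridding effect)"
                )

    def scaled(self, channels: int) -> int:
        return max(int(round(channels * self.width_mult)), 4)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["aspp_rates"] = {"rates": list(self.aspp_rates.rates), "kernel": self.aspp_rates.kernel}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "aspp_rates" in d and isinstance(d["aspp_rates"], dict):
            d["aspp_rates"] = DilationSet(
                tuple(d["aspp_rates"]["rates"]), d["aspp_rates"].get("kernel", 3)
            )
        elif "aspp_rates" in d:
            d["aspp_rates"] = DilationSet(tuple(d["aspp_rates"]))
        for key in ("deformable_stages", "decoder_channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)
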