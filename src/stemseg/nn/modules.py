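"""Layer abstractions over the autodiff core: parameter registry, train/eval
state, state-dict (de)serialization, and the handful of parameterized layers
the segmentation network is assembled from."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "DeformConv2d",
    "BatchNorm2d",
    "Linear",
    "set_seed",
    "get_rng",
]

_INIT_RNG = [np.random.default_rng(0)]


def set_seed(seed: int) -> None:
    """Seed the generator used for all subsequent weight initialization."""
    _INIT_RNG[0] = np.random.default_rng(seed)


def get_rng() -> np.random.Generator:
    return _INIT_RNG[0]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for cname, child in self._children.items():
            yield from child.named_buffers(prefix + cname + ".")

    def modules(self):
        yield self
        for child in self._children.values():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- serialization --------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: b for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own_params = dict(self.named_parameters())
        own_buffers = dict(self.named_buffers())
        missing = (set(own_params) | set(own_buffers)) - set(state)
        unexpected = set(state) - (set(own_params) | set(own_buffers))
        if strict and (missing or unexpected):
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} unexpected={sorted(unexpected)}")
        for name, p in own_params.items():
            if name in state:
                if p.data.shape != state[name].shape:
                    raise ValueError(f"shape mismatch for {name}")
                p.data = np.array(state[name], dtype=p.data.dtype)
        # buffers live on the owning module; walk children to set them in place
        for name in own_buffers:
            if name not in state:
                continue
            mod, leaf = self._resolve(name)
            mod._set_buffer(leaf, np.array(state[name]))
        return self

    def _resolve(self, dotted: str):
        mod = self
        parts = dotted.split(".")
        for part in parts[:-1]:
            mod = mod._children[part]
        return mod, parts[-1]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


def _he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
        zero_init: bool = False,
        dtype=np.float32,
    ):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        k = kernel_size
        fan_in = in_channels * k * k
        if zero_init:
            w = np.zeros((out_channels, in_channels, k, k), dtype=dtype)
        else:
            w = _he_normal(get_rng(), (out_channels, in_channels, k, k), fan_in, dtype)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class DeformConv2d(Module):
    """Deformable convolution with a parallel offset-predicting branch.

    The offset branch is an ordinary convolution of matching geometry whose
    weights start at zero, so a freshly built layer computes exactly the
    standard convolution and learns to displace its sampling grid from there.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int = 3,
        stride: int = 1,
        padding: int = 1,
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        k = kernel_size
        self.weight = Parameter(
            _he_normal(get_rng(), (out_channels, in_channels, k, k), in_channels * k * k, np.float32)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.offset_conv = Conv2d(
            in_channels, 2 * k * k, k, stride, padding, dilation, bias=True, zero_init=True
        )

    def forward(self, x: Tensor) -> Tensor:
        offsets = self.offset_conv(x)
        return F.deform_conv2d(
            x, self.weight, offsets, self.bias, self.stride, self.padding, self.dilation
        )


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_features, dtype=np.float32))
        self.beta = Parameter(np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(num_features, dtype=np.float32))
        self.register_buffer("running_var", np.ones(num_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            nhw = x.shape[0] * x.shape[2] * x.shape[3]
            unbias = nhw / max(nhw - 1, 1)
            self._set_buffer(
                "running_mean",
                ((1 - self.momentum) * self.running_mean + self.momentum * mu.data.reshape(c)).astype(np.float32),
            )
            self._set_buffer(
                "running_var",
                ((1 - self.momentum) * self.running_var + self.momentum * unbias * var.data.reshape(c)).astype(np.float32),
            )
            xhat = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            var = self.running_var.reshape(1, c, 1, 1)
            xhat = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, dtype=np.float32):
        super().__init__()
        self.weight = Parameter(_he_normal(get_rng(), (in_features, out_features), in_features, dtype))
        self.bias = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out
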