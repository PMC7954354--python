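"""Layer objects: parameter containers over the functional ops.

Weight initialisation is Kaiming-uniform (ReLU gain) with zero biases, drawn
from a caller-supplied ``numpy.random.Generator`` so that a model built twice
from the same seed has identical initial weights.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .autograd import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "Conv2d", "ConvTranspose2x2", "BatchNorm2d",
    "ReLU", "Sigmoid", "MaxPool2x2", "UpsampleBilinear2x", "ConvBNReLU",
]


class Module:
    """Minimal module base: parameter/buffer discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{name}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        buffers = getattr(self, "_buffers", None)
        if buffers:
            for name, value in buffers.items():
                yield (f"{prefix}{name}", value)
        for name, child in self._children():
            yield from child.named_buffers(prefix=f"{prefix}{name}.")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _pair(v):
    return tuple(v) if isinstance(v, (tuple, list)) else (v, v)


class Conv2d(Module):
    """Stride-1 convolution.  ``bias`` should be False when a BatchNorm
    follows: the norm's mean subtraction removes any bias shift, leaving the
    bias parameter with an identically zero gradient."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size,
                 padding=0, dilation=1, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = _pair(kernel_size)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.padding = _pair(padding)
        self.dilation = _pair(dilation)
        self.groups = groups
        fan_in = (in_channels // groups) * kh * kw
        bound = float(np.sqrt(6.0 / fan_in))
        self.weight = Parameter(rng.uniform(
            -bound, bound, (out_channels, in_channels // groups, kh, kw)
        ).astype(np.float32))
        self.bias = Parameter(np.zeros(out_channels, np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, padding=self.padding,
                        dilation=self.dilation, groups=self.groups)


class ConvTranspose2x2(Conv2d):
    """2x2 stride-1 transposed convolution (output grows by 1 per dim).

    Identical to a 2x2 convolution over a 1-padded input with flipped
    kernels; the kernel is stored directly in conv layout.
    """

    def __init__(self, in_channels, out_channels, bias=True, rng=None):
        super().__init__(in_channels, out_channels, kernel_size=2, padding=1,
                         bias=bias, rng=rng)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features, np.float32))
        self.beta = Parameter(np.zeros(num_features, np.float32))
        self._buffers = {
            "running_mean": np.zeros(num_features, np.float32),
            "running_var": np.ones(num_features, np.float32),
        }

    def forward(self, x):
        return F.batch_norm2d(
            x, self.gamma, self.beta, self.training,
            self._buffers["running_mean"], self._buffers["running_var"],
            momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return F.sigmoid(x)


class MaxPool2x2(Module):
    def forward(self, x):
        return F.max_pool2x2(x)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return F.upsample_bilinear2x(x)


class ConvBNReLU(Sequential):
    """Conv (no bias) -> BatchNorm -> ReLU, the default normalised conv layer."""

    def __init__(self, in_channels, out_channels, kernel_size=3, padding=1,
                 dilation=1, groups=1, rng=None):
        super().__init__(
            Conv2d(in_channels, out_channels, kernel_size, padding=padding,
                   dilation=dilation, groups=groups, bias=False, rng=rng),
            BatchNorm2d(out_channels),
            ReLU(),
        )
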