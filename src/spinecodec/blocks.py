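"""The three interchangeable convolution blocks the networks are built from.

* **standard** — the classic double conv: two 3x3 convolutions (stride 1,
  same padding), each followed by batch norm and ReLU.
* **DAB** (depth-wise asymmetric bottleneck) — a parameter-economic block:
  a 3x3 input convolution halves the channels, two parallel depth-wise
  branches each factorise a 3x3 kernel into 1x3 then 3x1 (one branch
  dilated), the branch sum passes through a 1x1 output convolution, and the
  block input is added back through a residual path (1x1-projected when the
  channel count changes).
* **MC** (micro codec) — a three-layer encode/decode-in-miniature: a 2x2
  valid convolution (shrinks each spatial dim by 1), a 2x2 stride-1
  transposed convolution (restores the size), then a 3x3 same-padded
  convolution; each layer has its own norm + activation.

All blocks preserve spatial size end to end.  During a forward pass each
block records the output of its size-preserving internal convolution layers
in ``self.taps`` (channel widths in ``self.tap_channels``); the dense
architectures concatenate these taps into the decoder at matching
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import ConfigurationError
from .nn import functional as F

__all__ = ["BlockSpec", "StandardBlock", "DABBlock", "MCBlock", "make_block",
           "BLOCK_KINDS"]

BLOCK_KINDS = ("standard", "dab", "mc")


@dataclass(frozen=True)
class BlockSpec:
    """Configuration of one convolution block."""

    kind: str
    in_channels: int
    out_channels: int
    dab_dilation: int = 2

    def __post_init__(self):
        if self.kind not in BLOCK_KINDS:
            raise ConfigurationError(
                f"unknown block kind {self.kind!r}; valid kinds: {BLOCK_KINDS}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")
        if self.kind == "dab" and self.in_channels % 2:
            raise ConfigurationError(
                f"DAB block requires an even number of input channels to halve "
                f"internally; got {self.in_channels}")
        if self.dab_dilation < 1:
            raise ConfigurationError("dab_dilation must be >= 1")


class _Block(nn.Module):
    """Common bookkeeping: channel check on entry, tap recording."""

    def __init__(self, spec: BlockSpec):
        super().__init__()
        self.spec = spec
        self.taps: list = []
        self.tap_channels: list[int] = []

    def _check_channels(self, x):
        c = x.shape[1]
        if c != self.spec.in_channels:
            raise ConfigurationError(
                f"{type(self).__name__} expects {self.spec.in_channels} input "
                f"channels, got {c}")


class StandardBlock(_Block):
    def __init__(self, spec: BlockSpec, rng: np.random.Generator):
        super().__init__(spec)
        cin, cout = spec.in_channels, spec.out_channels
        self.conv1 = nn.ConvBNReLU(cin, cout, 3, padding=1, rng=rng)
        self.conv2 = nn.ConvBNReLU(cout, cout, 3, padding=1, rng=rng)
        self.tap_channels = [cout, cout]

    def forward(self, x):
        self._check_channels(x)
        a = self.conv1(x)
        b = self.conv2(a)
        self.taps = [a, b]
        return b


class DABBlock(_Block):
    def __init__(self, spec: BlockSpec, rng: np.random.Generator):
        if spec.in_channels % 2:
            raise ConfigurationError(
                f"DAB block cannot halve odd channel count {spec.in_channels}")
        super().__init__(spec)
        cin, cout, d = spec.in_channels, spec.out_channels, spec.dab_dilation
        half = cin // 2
        self.inconv = nn.ConvBNReLU(cin, half, 3, padding=1, rng=rng)
        # branch A: depth-wise 1x3 then 3x1, dilation 1
        self.a1 = nn.ConvBNReLU(half, half, (1, 3), padding=(0, 1),
                                groups=half, rng=rng)
        self.a2 = nn.ConvBNReLU(half, half, (3, 1), padding=(1, 0),
                                groups=half, rng=rng)
        # branch B: same factorisation at the configured dilation
        self.b1 = nn.ConvBNReLU(half, half, (1, 3), padding=(0, d),
                                dilation=(1, d), groups=half, rng=rng)
        self.b2 = nn.ConvBNReLU(half, half, (3, 1), padding=(d, 0),
                                dilation=(d, 1), groups=half, rng=rng)
        self.outconv = nn.Conv2d(half, cout, 1, bias=False, rng=rng)
        self.outnorm = nn.BatchNorm2d(cout)
        self.project = (None if cin == cout
                        else nn.Conv2d(cin, cout, 1, rng=rng))
        self.tap_channels = [half, half, cout]

    def forward(self, x):
        self._check_channels(x)
        h = self.inconv(x)
        a = self.a2(self.a1(h))
        b = self.b2(self.b1(h))
        s = F.add(a, b)
        main = self.outnorm(self.outconv(s))
        res = x if self.project is None else self.project(x)
        out = F.relu(F.add(main, res))
        self.taps = [h, s, out]
        return out


class MCBlock(_Block):
    def __init__(self, spec: BlockSpec, rng: np.random.Generator):
        super().__init__(spec)
        cin, cout = spec.in_channels, spec.out_channels
        self.shrink = nn.Sequential(
            nn.Conv2d(cin, cout, 2, padding=0, bias=False, rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU())
        self.restore = nn.Sequential(
            nn.ConvTranspose2x2(cout, cout, bias=False, rng=rng),
            nn.BatchNorm2d(cout), nn.ReLU())
        self.refine = nn.ConvBNReLU(cout, cout, 3, padding=1, rng=rng)
        self.tap_channels = [cout, cout]

    def forward(self, x):
        self._check_channels(x)
        h, w = x.shape[2], x.shape[3]
        if h < 2 or w < 2:
            raise ValueError(
                f"input too small for 2x2 micro-codec: spatial dims {(h, w)}")
        a = self.shrink(x)       # (h-1, w-1)
        b = self.restore(a)      # back to (h, w)
        c = self.refine(b)
        self.taps = [b, c]       # only the size-preserving maps
        return c


_BLOCK_CLASSES = {"standard": StandardBlock, "dab": DABBlock, "mc": MCBlock}


def make_block(spec: BlockSpec, rng: np.random.Generator) -> _Block:
    """Instantiate the block named by ``spec.kind``."""
    return _BLOCK_CLASSES[spec.kind](spec, rng)
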