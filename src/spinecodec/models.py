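"""Multi-path codec segmentation architectures behind a single factory.

Four topologies, each assembled from one of the three convolution blocks and
optionally wired with dense skip fusion:

* **U**  — the classic encoder/decoder: ``depth`` pooling stages with
  channels doubling per stage, 2x2 max-pool downsampling, bilinear 2x
  upsampling, skip concatenation per level, 1x1 sigmoid head.
* **N**  — a precoding unit (a small encoder-decoder that returns to full
  resolution) whose output replaces the raw image as the U codec's input.
* **W1** — two parallel encoders and one decoder.  The primary encoder uses
  standard blocks; the secondary encoder and the decoder use the configured
  block.  The secondary's deepest map is concatenated with the primary's
  deepest map and 1x1-reduced before decoding; decoder skips come from the
  primary encoder.
* **W2** — one encoder (standard blocks) and two decoders (configured
  block).  The second decoder's input is the first decoder's first
  upsampled feature map; both run to full resolution and their outputs are
  concatenated before the head.

``dense=True`` records the output of every size-preserving convolution
layer inside each coding unit and concatenates those taps with the
matching-resolution decoder features, with a 1x1 channel reduction after
each dense merge.

Canonical names follow ``[Dense][DAB|MC][U|N|W1|W2]-Net`` (standard blocks
carry no block tag), e.g. ``DenseMCW1-Net``.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .blocks import BLOCK_KINDS, BlockSpec, make_block
from .errors import ConfigurationError, ShapeError
from .nn import functional as F

__all__ = ["ModelSpec", "SegmentationModel", "build_model", "parse_name",
           "list_variants", "count_parameters", "save_model", "load_model",
           "summary", "TOPOLOGIES"]

TOPOLOGIES = ("u", "n", "w1", "w2")
_BLOCK_TAG = {"standard": "", "dab": "DAB", "mc": "MC"}
_TOPO_TAG = {"u": "U", "n": "N", "w1": "W1", "w2": "W2"}


@dataclass(frozen=True)
class ModelSpec:
    """Names and sizes one network variant."""

    block: str = "standard"
    topology: str = "u"
    dense: bool = False
    depth: int = 4
    base_channels: int = 64
    in_channels: int = 1
    out_channels: int = 1
    seed: int = 0
    dab_dilation: int = 2

    def __post_init__(self):
        if self.block not in BLOCK_KINDS:
            raise ConfigurationError(
                f"unknown block {self.block!r}; valid: {BLOCK_KINDS}")
        if self.topology not in TOPOLOGIES:
            raise ConfigurationError(
                f"unknown topology {self.topology!r}; valid: {TOPOLOGIES}")
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.base_channels < 4:
            raise ConfigurationError("base_channels must be >= 4")
        if self.in_channels < 1 or self.out_channels < 1:
            raise ConfigurationError("channel counts must be positive")

    @property
    def name(self) -> str:
        dense = "Dense" if self.dense else ""
        return f"{dense}{_BLOCK_TAG[self.block]}{_TOPO_TAG[self.topology]}-Net"


def parse_name(name: str, **overrides) -> ModelSpec:
    """Invert :attr:`ModelSpec.name`; extra keyword arguments override sizes."""
    base = name
    if base.endswith("-Net"):
        base = base[:-4]
    dense = base.startswith("Dense")
    if dense:
        base = base[len("Dense"):]
    block = "standard"
    for kind, tag in _BLOCK_TAG.items():
        if tag and base.startswith(tag):
            block, base = kind, base[len(tag):]
            break
    topo = {v: k for k, v in _TOPO_TAG.items()}.get(base)
    if topo is None:
        valid = ", ".join(list_variants())
        raise ConfigurationError(
            f"cannot parse model name {name!r}; known variants: {valid}")
    return ModelSpec(block=block, topology=topo, dense=dense, **overrides)


def list_variants() -> list[str]:
    """The canonical published variants, in presentation order."""
    names = ["U-Net", "DABU-Net", "MCU-Net",
             "W1-Net", "W2-Net", "N-Net"]
    names += [f"{b}{t}-Net" for b in ("MC", "DAB") for t in ("W1", "W2", "N")]
    names += ["DenseU-Net"]
    names += [f"Dense{b}{t}-Net" for b in ("MC", "DAB") for t in ("W1", "W2", "N")]
    return names


# ---------------------------------------------------------------------------
# assembly pieces
# ---------------------------------------------------------------------------

class _Stage(nn.Module):
    """One codec stage: the configured block, with a standard 3x3 conv stem
    prepended when a DAB block would receive an odd channel count (DAB must
    halve its input internally, so e.g. the 1-channel image cannot feed it
    directly)."""

    def __init__(self, kind, cin, cout, rng, dab_dilation=2):
        super().__init__()
        self.stem = None
        if kind == "dab" and cin % 2:
            self.stem = nn.ConvBNReLU(cin, cout, 3, padding=1, rng=rng)
            cin = cout
        self.block = make_block(BlockSpec(kind, cin, cout, dab_dilation), rng)
        self.tap_channels = ([cout] if self.stem else []) + self.block.tap_channels
        self.taps: list = []

    def forward(self, x):
        pre = []
        if self.stem is not None:
            x = self.stem(x)
            pre = [x]
        y = self.block(x)
        self.taps = pre + self.block.taps
        return y


class _Encoder(nn.Module):
    """A coding unit: ``depth`` (block, 2x2 max-pool) stages, channels
    doubling per stage, optionally ending in a bottleneck block below the
    last pool."""

    def __init__(self, kind, cin, chs, rng, bottleneck=True,
                 bottleneck_kind=None, dab_dilation=2):
        super().__init__()
        depth = len(chs) - 1
        self.stages = [
            _Stage(kind, cin if l == 0 else chs[l - 1], chs[l], rng, dab_dilation)
            for l in range(depth)]
        self.bottleneck = (_Stage(bottleneck_kind or kind, chs[depth - 1],
                                  chs[depth], rng, dab_dilation)
                           if bottleneck else None)
        self.tap_channels = [st.tap_channels for st in self.stages]

    def forward(self, x):
        skips, taps = [], []
        for stage in self.stages:
            x = stage(x)
            skips.append(x)
            taps.append(stage.taps)
            x = F.max_pool2x2(x)
        if self.bottleneck is not None:
            x = self.bottleneck(x)
        return x, skips, taps


class _UpConv(nn.Module):
    """Bilinear 2x upsampling followed by a 3x3 conv reconciling channels."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv = nn.ConvBNReLU(cin, cout, 3, padding=1, rng=rng)

    def forward(self, x):
        return self.conv(F.upsample_bilinear2x(x))


class _Decoder(nn.Module):
    """A decoding unit running from the deepest map to full resolution.

    Per level (deep to shallow): upsample+conv, concatenate the encoder skip
    (if any) and the dense taps (if any), 1x1-reduce dense merges back to the
    level's nominal width, then the level block.
    """

    def __init__(self, kind, chs, rng, use_skips=True, tap_channels=None,
                 dab_dilation=2):
        super().__init__()
        depth = len(chs) - 1
        self.levels = list(reversed(range(depth)))
        self.use_skips = use_skips
        self.upconvs, self.reduces, self.blocks = [], [], []
        for l in self.levels:
            nominal = chs[l] * (2 if use_skips else 1)
            self.upconvs.append(_UpConv(chs[l + 1], chs[l], rng))
            if tap_channels is not None:
                extra = sum(tap_channels[l])
                self.reduces.append(nn.ConvBNReLU(nominal + extra, nominal, 1,
                                                  padding=0, rng=rng))
            else:
                self.reduces.append(None)
            self.blocks.append(_Stage(kind, nominal, chs[l], rng, dab_dilation))

    def forward(self, x, skips=None, taps=None):
        first_up = None
        for i, l in enumerate(self.levels):
            x = self.upconvs[i](x)
            if first_up is None:
                first_up = x
            feats = [x]
            if self.use_skips:
                feats.append(skips[l])
            if self.reduces[i] is not None:
                x = self.reduces[i](F.concat(feats + list(taps[l])))
            elif len(feats) > 1:
                x = F.concat(feats)
            x = self.blocks[i](x)
        return x, first_up


class _TailDecoder(nn.Module):
    """W2's second decoding unit: starts from the first decoder's first
    upsampled feature map (one level below full depth) and runs skip-free to
    full resolution."""

    def __init__(self, kind, chs, rng, tap_channels=None, dab_dilation=2):
        super().__init__()
        depth = len(chs) - 1
        top = depth - 1
        self.levels = [top] + list(reversed(range(top)))
        self.upconvs, self.reduces, self.blocks = [], [], []
        for l in self.levels:
            self.upconvs.append(None if l == top else
                                _UpConv(chs[l + 1], chs[l], rng))
            if tap_channels is not None:
                extra = sum(tap_channels[l])
                self.reduces.append(nn.ConvBNReLU(chs[l] + extra, chs[l], 1,
                                                  padding=0, rng=rng))
            else:
                self.reduces.append(None)
            self.blocks.append(_Stage(kind, chs[l], chs[l], rng, dab_dilation))

    def forward(self, x, taps=None):
        for i, l in enumerate(self.levels):
            if self.upconvs[i] is not None:
                x = self.upconvs[i](x)
            if self.reduces[i] is not None:
                x = self.reduces[i](F.concat([x] + list(taps[l])))
            x = self.blocks[i](x)
        return x


class _Precoder(nn.Module):
    """N topology's precoding unit: a 2-stage mini encoder-decoder that
    alternates block+pool then upsamples back to the input resolution,
    emitting ``base`` feature maps that replace the raw image as the main
    codec's input."""

    def __init__(self, kind, cin, base, rng, dab_dilation=2):
        super().__init__()
        self.stage1 = _Stage(kind, cin, base, rng, dab_dilation)
        self.stage2 = _Stage(kind, base, 2 * base, rng, dab_dilation)
        self.upconv = _UpConv(2 * base, base, rng)
        self.merge = nn.ConvBNReLU(2 * base, base, 1, padding=0, rng=rng)

    def forward(self, x):
        a = self.stage1(x)
        b = self.stage2(F.max_pool2x2(a))
        u = self.upconv(b)
        return self.merge(F.concat([u, a]))


class _Head(nn.Module):
    """1x1 convolution + sigmoid producing the probability map.

    The sigmoid is clamped to [1e-7, 1 - 1e-7]: float32 saturates to exact
    0/1 for |logit| > ~17, which would violate the open-interval output
    contract (and the BCE loss clamps at the same bounds anyway)."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 1, bias=True, rng=rng)

    def forward(self, x):
        return F.clamp(F.sigmoid(self.conv(x)), F.BCE_EPS, 1.0 - F.BCE_EPS)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class SegmentationModel(nn.Module):
    """An assembled variant.  ``forward`` maps (N, in_channels, H, W) to a
    probability map of identical spatial size with values in (0, 1); H and W
    must be divisible by ``2**depth``."""

    def __init__(self, spec: ModelSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d = spec.dab_dilation
        chs = [spec.base_channels * 2 ** l for l in range(spec.depth + 1)]
        self._chs = chs
        kind, topo, dense = spec.block, spec.topology, spec.dense

        if topo in ("u", "n"):
            cin = spec.in_channels
            if topo == "n":
                self.precoder = _Precoder(kind, cin, chs[0], rng, d)
                cin = chs[0]
            self.encoder = _Encoder(kind, cin, chs, rng, dab_dilation=d)
            taps = self.encoder.tap_channels if dense else None
            self.decoder = _Decoder(kind, chs, rng, tap_channels=taps,
                                    dab_dilation=d)
            self.head = _Head(chs[0], spec.out_channels, rng)
        elif topo == "w1":
            self.encoder = _Encoder("standard", spec.in_channels, chs, rng)
            self.encoder2 = _Encoder(kind, spec.in_channels, chs, rng,
                                     bottleneck=False, dab_dilation=d)
            self.merge = nn.ConvBNReLU(chs[-1] + chs[-2], chs[-1], 1,
                                       padding=0, rng=rng)
            taps = ([p + s for p, s in zip(self.encoder.tap_channels,
                                           self.encoder2.tap_channels)]
                    if dense else None)
            self.decoder = _Decoder(kind, chs, rng, tap_channels=taps,
                                    dab_dilation=d)
            self.head = _Head(chs[0], spec.out_channels, rng)
        else:  # w2
            self.encoder = _Encoder("standard", spec.in_channels, chs, rng)
            taps = self.encoder.tap_channels if dense else None
            self.decoder = _Decoder(kind, chs, rng, tap_channels=taps,
                                    dab_dilation=d)
            self.decoder2 = _TailDecoder(kind, chs, rng, tap_channels=taps,
                                         dab_dilation=d)
            self.head = _Head(2 * chs[0], spec.out_channels, rng)

    # -- contracts ---------------------------------------------------------
    def _check_input(self, x):
        if x.ndim != 4:
            raise ShapeError(f"expected NCHW input, got shape {x.shape}")
        if x.shape[1] != self.spec.in_channels:
            raise ConfigurationError(
                f"{self.spec.name} expects {self.spec.in_channels} input "
                f"channels, got {x.shape[1]}")
        div = 2 ** self.spec.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise ShapeError(
                f"spatial dims {x.shape[2:]} must be divisible by {div} "
                f"(depth {self.spec.depth})")

    def forward(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        self._check_input(x)
        topo, dense = self.spec.topology, self.spec.dense
        if topo in ("u", "n"):
            if topo == "n":
                x = self.precoder(x)
            deep, skips, taps = self.encoder(x)
            out, _ = self.decoder(deep, skips, taps if dense else None)
        elif topo == "w1":
            deep1, skips, taps1 = self.encoder(x)
            deep2, _, taps2 = self.encoder2(x)
            merged = self.merge(F.concat([deep1, deep2]))
            taps = ([p + s for p, s in zip(taps1, taps2)] if dense else None)
            out, _ = self.decoder(merged, skips, taps)
        else:  # w2
            deep, skips, taps = self.encoder(x)
            taps = taps if dense else None
            out1, first_up = self.decoder(deep, skips, taps)
            out2 = self.decoder2(first_up, taps)
            out = F.concat([out1, out2])
        return self.head(out)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward on a plain array; returns probabilities."""
        was_training = self.training
        self.eval()
        try:
            out = self.forward(nn.Tensor(np.asarray(x, dtype=np.float32)))
        finally:
            self.train(was_training)
        return out.data

    @property
    def name(self) -> str:
        return self.spec.name


def build_model(spec: ModelSpec) -> SegmentationModel:
    return SegmentationModel(spec)


def count_parameters(model: nn.Module) -> int:
    return int(sum(p.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# persistence / reporting
# ---------------------------------------------------------------------------

def save_model(model: SegmentationModel, path) -> None:
    """Serialise weights, norm buffers and the ModelSpec (as JSON) to .npz."""
    arrays = {f"p/{n}": p.data for n, p in model.named_parameters()}
    arrays.update({f"b/{n}": v for n, v in model.named_buffers()})
    with open(path, "wb") as fh:
        np.savez(fh, spec_json=json.dumps(asdict(model.spec)), **arrays)


def load_model(path) -> SegmentationModel:
    with np.load(path, allow_pickle=False) as z:
        spec = ModelSpec(**json.loads(str(z["spec_json"])))
        model = build_model(spec)
        for n, p in model.named_parameters():
            stored = z[f"p/{n}"]
            if stored.shape != p.data.shape:
                raise ConfigurationError(
                    f"checkpoint/spec mismatch for parameter {n}: "
                    f"{stored.shape} vs {p.data.shape}")
            p.data[...] = stored
        for n, b in model.named_buffers():
            b[...] = z[f"b/{n}"]
    return model


def summary(model: SegmentationModel) -> str:
    """Plain-text architecture summary: one line per parameter."""
    buf = io.StringIO()
    buf.write(f"{model.spec.name}  (block={model.spec.block}, "
              f"topology={model.spec.topology}, dense={model.spec.dense}, "
              f"depth={model.spec.depth}, base={model.spec.base_channels})\n")
    total = 0
    for name, p in model.named_parameters():
        buf.write(f"  {name:60s} {str(p.shape):20s} {p.size:>10d}\n")
        total += p.size
    buf.write(f"  {'total trainable parameters':60s} {'':20s} {total:>10d}\n")
    return buf.getvalue()
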