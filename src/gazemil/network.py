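"""Grid-logit encoder and per-label decoder.

The encoder maps a letterboxed grayscale image to one logit per grid
cell per label (a 32x32 grid at the 512-px working resolution, i.e.
input/16). Its classification head replaces global pooling + linear
layer with two convolutions separated by batch normalization and ReLU,
so predictions stay spatial. With ``multi_resolution`` enabled, the
output of every trunk stage is resampled bilinearly to grid resolution
and concatenated before the head, giving the head access to
fine-resolution evidence for small findings.

Two trunks are provided: ``tiny`` (four strided conv blocks, < 500k
parameters, the desk-scale default used throughout the tests) and
``resnet50_shaped`` (bottleneck stages shaped like ResNet-50, for
full-scale runs; supported via config but not exercised at desk scale).

The decoder upsamples the head's input features through three blocks of
(bilinear x2 upsample, convolution, batch normalization) to half the
working resolution, with one output channel per label; its sigmoid maps
are the model's high-resolution localization output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concatenate
from .nn import AMSGrad  # noqa: F401  (re-exported for convenience)
from .nn import BatchNorm2d, Conv2d, Module, bilinear_resize, maxpool2d
from .report_labeler import STUDY_LABELS

#: Encoder downsampling factor from input to grid resolution.
GRID_STRIDE = 16


@dataclass(frozen=True)
class EncoderConfig:
    backbone: str = "tiny"
    input_size: int = 512
    n_classes: int = len(STUDY_LABELS)
    multi_resolution: bool = True
    tiny_channels: tuple[int, ...] = (8, 16, 32, 64)
    head_channels: int = 64
    decoder_channels: tuple[int, int] = (32, 16)

    def __post_init__(self) -> None:
        if self.backbone not in ("tiny", "resnet50_shaped"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.input_size % GRID_STRIDE:
            raise ValueError(
                f"input size {self.input_size} not divisible by {GRID_STRIDE}"
            )

    @property
    def grid_size(self) -> int:
        return self.input_size // GRID_STRIDE

    @property
    def decoder_size(self) -> int:
        return self.input_size // 2


@dataclass
class ModelOutputs:
    """Forward-pass outputs; arrays are tape tensors during training."""

    grid_logits: Tensor
    decoder_logits: Tensor

    @property
    def spatial_activation(self) -> np.ndarray:
        """sigma(grid logits): per-cell class probabilities in (0, 1)."""
        from scipy.special import expit

        return expit(self.grid_logits.value)


class _ConvBNReLU(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, kernel, stride=stride, rng=rng, bias=False)
        self.bn = BatchNorm2d(cout)

    def forward(self, x):
        return self.bn(self.conv(x)).relu()


class _TinyTrunk(Module):
    """Four strided conv blocks; returns per-stage feature taps."""

    def __init__(self, channels, rng):
        super().__init__()
        cin = 1
        self.blocks = []
        for cout in channels:
            self.blocks.append(_ConvBNReLU(cin, cout, stride=2, rng=rng))
            cin = cout
        self.tap_channels = tuple(channels)

    def forward(self, x):
        taps = []
        for block in self.blocks:
            x = block(x)
            taps.append(x)
        return taps


class _Bottleneck(Module):
    def __init__(self, cin, cmid, cout, stride, rng):
        super().__init__()
        self.conv1 = Conv2d(cin, cmid, 1, rng=rng, bias=False)
        self.bn1 = BatchNorm2d(cmid)
        self.conv2 = Conv2d(cmid, cmid, 3, stride=stride, rng=rng, bias=False)
        self.bn2 = BatchNorm2d(cmid)
        self.conv3 = Conv2d(cmid, cout, 1, rng=rng, bias=False)
        self.bn3 = BatchNorm2d(cout)
        self.project = (
            None
            if stride == 1 and cin == cout
            else Conv2d(cin, cout, 1, stride=stride, rng=rng, bias=False)
        )
        self.bn_proj = None if self.project is None else BatchNorm2d(cout)

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = x if self.project is None else self.bn_proj(self.project(x))
        return (out + shortcut).relu()


class _ResNet50Trunk(Module):
    """Bottleneck trunk shaped like ResNet-50 (stages 3-4-6-3)."""

    def __init__(self, rng):
        super().__init__()
        self.stem = _ConvBNReLU(1, 64, kernel=7, stride=2, rng=rng)
        widths = (256, 512, 1024, 2048)
        depths = (3, 4, 6, 3)
        strides = (1, 2, 2, 2)
        cin = 64
        self.stages = []
        for cout, depth, stride in zip(widths, depths, strides):
            blocks = [_Bottleneck(cin, cout // 4, cout, stride, rng)]
            blocks += [
                _Bottleneck(cout, cout // 4, cout, 1, rng) for _ in range(depth - 1)
            ]
            self.stages.append(blocks)
            cin = cout
        self.stage_list = [b for stage in self.stages for b in stage]
        self.tap_channels = widths

    def forward(self, x):
        x = maxpool2d(self.stem(x), kernel=3, stride=2, pad=1)
        taps = []
        for stage in self.stages:
            for block in stage:
                x = block(x)
            taps.append(x)
        return taps


class Encoder(Module):
    """Trunk + multi-resolution fusion + two-convolution grid head."""

    def __init__(self, config: EncoderConfig, rng=None):
        super().__init__()
        self.config = config
        rng = rng or np.random.default_rng()
        if config.backbone == "tiny":
            self.trunk = _TinyTrunk(config.tiny_channels, rng)
        else:
            self.trunk = _ResNet50Trunk(rng)
        taps = self.trunk.tap_channels
        self.fused_channels = sum(taps) if config.multi_resolution else taps[-1]
        # classification head: two convolutions separated by BN + ReLU
        self.head_conv1 = Conv2d(self.fused_channels, config.head_channels, 3, rng=rng)
        self.head_bn = BatchNorm2d(config.head_channels)
        self.head_conv2 = Conv2d(config.head_channels, config.n_classes, 1, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        """Grid-resolution feature map feeding the head and decoder."""
        size = self.config.input_size
        if x.value.ndim != 4 or x.value.shape[2:] != (size, size):
            raise ValueError(
                f"expected input (N, 1, {size}, {size}), got {x.value.shape}"
            )
        taps = self.trunk(x)
        g = self.config.grid_size
        if self.config.multi_resolution:
            resized = [
                t if t.value.shape[2:] == (g, g) else bilinear_resize(t, (g, g))
                for t in taps
            ]
            return concatenate(resized, axis=1)
        t = taps[-1]
        return t if t.value.shape[2:] == (g, g) else bilinear_resize(t, (g, g))

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        feats = self.features(x)
        logits = self.head_conv2(self.head_bn(self.head_conv1(feats)).relu())
        return feats, logits


class Decoder(Module):
    """Three (upsample x2, conv, BN) blocks to half working resolution."""

    def __init__(self, in_channels: int, config: EncoderConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        c1, c2 = config.decoder_channels
        self.block1 = _ConvBNReLU(in_channels, c1, rng=rng)
        self.block2 = _ConvBNReLU(c1, c2, rng=rng)
        self.conv3 = Conv2d(c2, config.n_classes, 3, rng=rng, bias=False)
        self.bn3 = BatchNorm2d(config.n_classes)

    def forward(self, feats: Tensor) -> Tensor:
        h = feats.value.shape[2]
        x = self.block1(bilinear_resize(feats, (2 * h, 2 * h)))
        x = self.block2(bilinear_resize(x, (4 * h, 4 * h)))
        x = self.bn3(self.conv3(bilinear_resize(x, (8 * h, 8 * h))))
        return x


class GazeMILNet(Module):
    """Encoder + decoder producing grid logits and per-label maps."""

    def __init__(self, config: EncoderConfig = EncoderConfig(), seed: int | None = None):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = Encoder(config, rng)
        self.decoder = Decoder(self.encoder.fused_channels, config, rng)

    def forward(self, x) -> ModelOutputs:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        feats, grid_logits = self.encoder(x)
        decoder_logits = self.decoder(feats)
        return ModelOutputs(grid_logits=grid_logits, decoder_logits=decoder_logits)

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.parameters())


def save_checkpoint(model: GazeMILNet, path) -> None:
    """Save weights (npz) with the config embedded."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> GazeMILNet:
    data = np.load(path, allow_pickle=False)
    raw = json.loads(bytes(data["__config__"]).decode())
    for key in ("tiny_channels", "decoder_channels"):
        raw[key] = tuple(raw[key])
    model = GazeMILNet(EncoderConfig(**raw))
    model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
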