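"""Backbone family for patch classification and lesion segmentation.

The classifier is a ResNet50-style bottleneck network with three optional
modifications, each a config switch so every ablation variant is
constructible from configuration alone:

* **SampleInput stem** — the usual 7x7/stride-2 input convolution replaced
  by three stacked 3x3 convolutions.  The stride-2 convolution is the last
  of the three, which makes the composite receptive field exactly 7x7 while
  keeping the overall downsampling factor of 2.
* **DARes stages** — selected stages are wrapped in an outer residual that
  adds a projection of the stage input (shallow features) and a projection
  of the middle block's output (mid features) onto the stage output (deep
  features) before the final activation: a double-layer nested residual.
* **SPP head** — spatial pyramid pooling over a set of grid sizes produces
  a fixed-length vector (channels x sum of squared levels) for any input
  spatial size, so one parameter set serves multiple input resolutions.

Both width (channel multiplier) and depth (blocks per stage) are scalable
so that miniature variants train on a CPU in minutes; ``miniature_config``
is the preset the test-scale experiments use.  A plain encoder-decoder
U-Net with skip connections covers the per-class lesion segmentation stage.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

VALID_STAGES = ("layer2", "layer3", "layer4")


@dataclasses.dataclass
class ModelConfig:
    n_classes: int = 4
    dares_layers: tuple[str, ...] = ("layer2", "layer4")
    use_sample_input: bool = True
    use_spp: bool = True
    spp_levels: tuple[int, ...] = (1, 2, 4)
    n_attention_maps: int = 32
    width_multiplier: float = 1.0
    input_size: int = 512
    stage_blocks: tuple[int, ...] = (3, 4, 6, 3)

    def __post_init__(self) -> None:
        bad = set(self.dares_layers) - set(VALID_STAGES)
        if bad:
            raise ValueError(f"invalid DARes stage name(s): {sorted(bad)}")
        if self.n_attention_maps < 1:
            raise ValueError("n_attention_maps must be >= 1")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0,1]")
        if self.use_spp and not self.spp_levels:
            raise ValueError("spp_levels must be nonempty")
        if len(self.stage_blocks) != 4:
            raise ValueError("stage_blocks must have 4 entries")

    def base_width(self) -> int:
        return max(4, int(round(64 * self.width_multiplier)))


def miniature_config(n_classes: int = 4, **overrides) -> ModelConfig:
    """Desk-scale preset: width 1/8, one bottleneck per stage, 64-px input."""
    kw = dict(
        n_classes=n_classes, width_multiplier=0.125, stage_blocks=(1, 1, 1, 1),
        spp_levels=(1, 2), n_attention_maps=4, input_size=64,
    )
    kw.update(overrides)
    return ModelConfig(**kw)


# ---------------------------------------------------------------------------
# stem


def build_sample_input(cfg: ModelConfig, rng: np.random.Generator) -> nn.Module:
    """Input stem: 3 -> base_width channels, overall stride 2.

    With the SampleInput switch on, three 3x3 conv-bn-relu blocks with the
    stride-2 convolution last (composite receptive field 7x7); otherwise a
    single 7x7/stride-2 block producing the same output shape.
    """
    w = cfg.base_width()
    if cfg.use_sample_input:
        return nn.Sequential(
            nn.conv_bn_relu(3, w, 3, stride=1, padding=1, rng=rng),
            nn.conv_bn_relu(w, w, 3, stride=1, padding=1, rng=rng),
            nn.conv_bn_relu(w, w, 3, stride=2, padding=1, rng=rng),
        )
    return nn.conv_bn_relu(3, w, 7, stride=2, padding=3, rng=rng)


# ---------------------------------------------------------------------------
# residual stages


class Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, cin: int, width: int, stride: int, *, rng: np.random.Generator):
        cout = width * self.expansion
        self.conv1 = nn.Conv2d(cin, width, 1, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(width)
        self.conv2 = nn.Conv2d(width, width, 3, stride=stride, padding=1,
                               bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(width)
        self.conv3 = nn.Conv2d(width, cout, 1, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(cout)
        if stride != 1 or cin != cout:
            self.proj = nn.Sequential(
                nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
                nn.BatchNorm2d(cout),
            )
        else:
            self.proj = nn.Identity()

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = self.bn3(self.conv3(h))
        return (h + self.proj(x)).relu()


class Stage(nn.Module):
    """A vanilla ResNet stage: ``n_blocks`` bottlenecks, stride on the first."""

    def __init__(self, cin: int, width: int, n_blocks: int, stride: int,
                 *, rng: np.random.Generator):
        cout = width * Bottleneck.expansion
        blocks = [Bottleneck(cin, width, stride, rng=rng)]
        blocks += [Bottleneck(cout, width, 1, rng=rng) for _ in range(n_blocks - 1)]
        self.blocks = blocks
        self.cout = cout

    def forward(self, x: Tensor) -> Tensor:
        for b in self.blocks:
            x = b(x)
        return x


class DAResStage(nn.Module):
    """Double-layer nested residual stage.

    The inner layer is the ordinary bottleneck stack; the outer layer adds a
    1x1 projection of the stage input and a 1x1 projection of the middle
    block's output onto the stack output before a final ReLU, fusing shallow,
    middle and deep features.  Output shape equals the vanilla stage's.
    """

    def __init__(self, cin: int, width: int, n_blocks: int, stride: int,
                 *, rng: np.random.Generator):
        self.inner = Stage(cin, width, n_blocks, stride, rng=rng)
        cout = self.inner.cout
        self.cout = cout
        self.mid_index = (n_blocks + 1) // 2  # 1-based ceil(k/2)
        self.proj_in = nn.Sequential(
            nn.Conv2d(cin, cout, 1, stride=stride, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
        )
        self.proj_mid = nn.Sequential(
            nn.Conv2d(cout, cout, 1, bias=False, rng=rng),
            nn.BatchNorm2d(cout),
        )

    def project_input(self, x: Tensor) -> Tensor:
        return self.proj_in(x)

    def forward(self, x: Tensor) -> Tensor:
        h = x
        mid = None
        for i, block in enumerate(self.inner.blocks, start=1):
            h = block(h)
            if i == self.mid_index:
                mid = h
        return (h + self.proj_in(x) + self.proj_mid(mid)).relu()


def build_dares_block(stage: str, cfg: ModelConfig,
                      rng: np.random.Generator | None = None) -> nn.Module:
    """Build the named stage as a DARes stage (drop-in for the vanilla one)."""
    if stage not in VALID_STAGES:
        raise ValueError(f"stage must be one of {VALID_STAGES}, got {stage!r}")
    rng = rng or np.random.default_rng(0)
    b = cfg.base_width()
    idx = {"layer2": 1, "layer3": 2, "layer4": 3}[stage]
    widths = [b, 2 * b, 4 * b, 8 * b]
    cin = widths[idx - 1] * Bottleneck.expansion
    return DAResStage(cin, widths[idx], cfg.stage_blocks[idx], 2, rng=rng)


# ---------------------------------------------------------------------------
# SPP head


class SPPBlock(nn.Module):
    """Spatial pyramid pooling: fixed-length vector for any input size.

    Output length = channels x sum(level^2); inputs smaller than the largest
    grid are rejected.
    """

    def __init__(self, levels: tuple[int, ...]):
        if not levels:
            raise ValueError("spp_levels must be nonempty")
        self.levels = tuple(levels)

    def output_multiplier(self) -> int:
        return sum(g * g for g in self.levels)

    def forward(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        pooled = [x.adaptive_avg_pool(g).reshape(n, -1) for g in self.levels]
        return nn.concat(pooled, axis=1)


def build_spp(cfg: ModelConfig) -> SPPBlock:
    return SPPBlock(cfg.spp_levels)


# ---------------------------------------------------------------------------
# full classifier


class WSACResNet(nn.Module):
    """ResNet50-skeleton classifier with optional stem/DARes/SPP switches.

    Exposes both the last-stage feature map (for the attention head) and the
    class logits via :meth:`forward_features`.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        b = cfg.base_width()
        self.stem = build_sample_input(cfg, rng)
        self.pool = nn.MaxPool2()
        widths = [b, 2 * b, 4 * b, 8 * b]
        strides = [1, 2, 2, 2]
        stages: list[nn.Module] = []
        cin = b
        for i, (w, k, s) in enumerate(zip(widths, cfg.stage_blocks, strides)):
            name = f"layer{i + 1}"
            cls = DAResStage if name in cfg.dares_layers else Stage
            stage = cls(cin, w, k, s, rng=rng)
            stages.append(stage)
            cin = stage.cout
        self.stages = stages
        self.feature_channels = cin
        if cfg.use_spp:
            self.spp = build_spp(cfg)
            fc_in = cin * self.spp.output_multiplier()
        else:
            self.spp = None
            fc_in = cin
        self.fc = nn.Linear(fc_in, cfg.n_classes, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        h = self.pool(self.stem(x))
        for stage in self.stages:
            h = stage(h)
        return h

    def head(self, fmap: Tensor) -> Tensor:
        if self.spp is not None:
            v = self.spp(fmap)
        else:
            v = fmap.adaptive_avg_pool(1).reshape(fmap.shape[0], -1)
        return self.fc(v)

    def forward_features(self, x: Tensor) -> tuple[Tensor, Tensor]:
        fmap = self.features(x)
        return fmap, self.head(fmap)

    def forward(self, x: Tensor) -> Tensor:
        return self.forward_features(x)[1]


def build_backbone(cfg: ModelConfig, seed: int = 0) -> WSACResNet:
    return WSACResNet(cfg, seed=seed)


def plain_student_config(cfg: ModelConfig) -> ModelConfig:
    """The student is the unmodified skeleton: no DARes, stock stem, no SPP."""
    return dataclasses.replace(cfg, dares_layers=(), use_sample_input=False,
                               use_spp=False)


# ---------------------------------------------------------------------------
# U-Net


class _DoubleConv(nn.Module):
    def __init__(self, cin: int, cout: int, *, rng: np.random.Generator):
        self.block = nn.Sequential(
            nn.conv_bn_relu(cin, cout, 3, padding=1, rng=rng),
            nn.conv_bn_relu(cout, cout, 3, padding=1, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)


class UNet(nn.Module):
    """Standard encoder-decoder with skip connections; per-pixel lesion logit
    map at input resolution.  Input spatial dims must be divisible by
    2**depth."""

    def __init__(self, n_channels: int = 3, base_width: int = 16,
                 depth: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        widths = [base_width * 2 ** i for i in range(depth + 1)]
        self.enc = [_DoubleConv(n_channels if i == 0 else widths[i - 1], widths[i],
                                rng=rng) for i in range(depth)]
        self.bottom = _DoubleConv(widths[depth - 1], widths[depth], rng=rng)
        self.up_convs = [nn.Conv2d(widths[i + 1], widths[i], 1, rng=rng)
                         for i in reversed(range(depth))]
        self.dec = [_DoubleConv(2 * widths[i], widths[i], rng=rng)
                    for i in reversed(range(depth))]
        self.final = nn.Conv2d(widths[0], 1, 1, rng=rng)
        self.pool = nn.MaxPool2()

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[1], x.shape[2]
        if h % (2 ** self.depth) or w % (2 ** self.depth):
            raise ValueError(
                f"input {h}x{w} not divisible by 2^{self.depth}")
        skips = []
        for enc in self.enc:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottom(x)
        for up, dec, skip in zip(self.up_convs, self.dec, reversed(skips)):
            x = up(x.upsample_nearest2())
            x = dec(nn.concat([skip, x], axis=3))
        return self.final(x)


def build_unet(n_channels: int = 3, base_width: int = 16, depth: int = 3,
               seed: int = 0) -> UNet:
    return UNet(n_channels=n_channels, base_width=base_width, depth=depth, seed=seed)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: nn.Module, path: str | Path,
                    cfg: ModelConfig | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = model.state_arrays()
    np.savez(path, **{f"a{i}": a for i, a in enumerate(arrays)})
    if cfg is not None:
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps(dataclasses.asdict(cfg), indent=2))


def load_checkpoint(model: nn.Module, path: str | Path) -> nn.Module:
    path = Path(path)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    with np.load(path) as data:
        arrays = [data[f"a{i}"] for i in range(len(data.files))]
    model.load_state_arrays(arrays)
    return model


def load_model_config(path: str | Path) -> ModelConfig:
    d = json.loads(Path(path).read_text())
    for key in ("dares_layers", "spp_levels", "stage_blocks"):
        if key in d:
            d[key] = tuple(d[key])
    return ModelConfig(**d)
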