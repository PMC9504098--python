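"""Model assembly: the full fusion network and a plain U-Net baseline.

The fusion network runs the CNN and transformer branches in parallel on
the C-channel input stack, bridges their three-level feature maps through
the multiple-parallel-fusion module, and maps the finest fused features
(H/4) through a 1×1 prediction head, bilinear upsampling and a sigmoid to
a K=3-channel fluorescence prediction in [0, 1] at full resolution.

The baseline is a standard 4-level encoder–decoder with skip
concatenations and the same output contract, used as the comparison
model in evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .cnn_branch import CnnBranch, CnnConfig
from .transformer_branch import TransformerBranch, TransformerConfig
from .fusion import MPFFusion, FusionConfig
from .nn import Module, Conv2d, BatchNorm2d, Sequential, ReLU, UpsampleNearest2d
from .nn import autograd as ag
from .nn.autograd import Tensor

__all__ = ["ModelConfig", "MPFNet", "UNetBaseline", "build_model",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Everything needed to (re)build a network deterministically."""

    in_channels: int = 10
    out_channels: int = 3
    image_size: int = 128
    seed: int = 0
    arch: str = "mpfnet"                     # "mpfnet" or "unet"
    cnn: CnnConfig = field(default_factory=CnnConfig)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    unet_base_width: int = 32

    def __post_init__(self):
        self.transformer.image_size = self.image_size

    @classmethod
    def reduced(cls, image_size: int = 64, in_channels: int = 10,
                seed: int = 0, arch: str = "mpfnet") -> "ModelConfig":
        """Narrow configuration for CPU-scale experiments."""
        return cls(
            in_channels=in_channels, image_size=image_size, seed=seed, arch=arch,
            cnn=CnnConfig(stage_channels=(8, 16, 32, 64), blocks_per_stage=1),
            transformer=TransformerConfig(
                image_size=image_size, embed_dim=64, n_heads=4, depth=8,
                mlp_ratio=2.0, dropout=0.1, decoder_channels=(64, 32, 16)),
            fusion=FusionConfig(level_widths=(64, 32, 16)),
            unet_base_width=8,
        )

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("stage_channels",):
            d["cnn"][key] = list(d["cnn"][key])
        d["transformer"]["decoder_channels"] = list(d["transformer"]["decoder_channels"])
        d["fusion"]["level_widths"] = list(d["fusion"]["level_widths"])
        d["fusion"]["spatial_kernels"] = list(d["fusion"]["spatial_kernels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        # rebuild nested configs with tuple fields restored
        raw_c = d.pop("cnn", {})
        if raw_c:
            raw_c["stage_channels"] = tuple(raw_c["stage_channels"])
        cnn = CnnConfig(**raw_c) if raw_c else CnnConfig()
        raw_t = d.pop("transformer", {})
        if raw_t:
            raw_t["decoder_channels"] = tuple(raw_t["decoder_channels"])
        transformer = TransformerConfig(**raw_t) if raw_t else TransformerConfig()
        raw_f = d.pop("fusion", {})
        if raw_f:
            raw_f["level_widths"] = tuple(raw_f["level_widths"])
            raw_f["spatial_kernels"] = tuple(raw_f["spatial_kernels"])
        fusion = FusionConfig(**raw_f) if raw_f else FusionConfig()
        return cls(cnn=cnn, transformer=transformer, fusion=fusion, **d)


class MPFNet(Module):
    """Two-branch encoder with attention fusion and a skip-refined head.

    After the gated coarse→fine cascade ends at H/4, the decoder's
    upsampling path jump-connects the encoder CNN's half- and full-
    resolution feature maps (two nearest-upsample + concat + 3×3 conv
    steps) so the prediction recovers pixel-scale detail, then a 1×1
    convolution and sigmoid emit the K-channel fluorescence estimate.
    """

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.cnn = CnnBranch(cfg.in_channels, cfg.cnn, rng)
        self.transformer = TransformerBranch(cfg.in_channels, cfg.transformer, rng)
        c1, c2, c3, c4 = cfg.cnn.stage_channels
        self.fusion = MPFFusion(
            s_channels=cfg.transformer.decoder_channels,
            h_channels=(c4, c3, c2),   # (H/16, H/8, H/4) order
            cfg=cfg.fusion, rng=rng)
        l2 = cfg.fusion.level_widths[2]
        self.refine_half = Sequential(Conv2d(l2 + c1, l2, 3, rng),
                                      BatchNorm2d(l2))    # H/2, skip = transition
        self.refine_full = Sequential(Conv2d(l2 + c1, l2, 3, rng),
                                      BatchNorm2d(l2))    # H,   skip = stage 1
        self.head = Conv2d(l2, cfg.out_channels, 1, rng, padding=0)
        self.head.weight.data *= 0.1   # keep initial logits near 0 (sigmoid unsaturated)

    def forward(self, x) -> Tensor:
        x = ag.as_tensor(x)
        pyramid, (full, half) = self.cnn.forward_with_skips(x)
        maps = self.transformer(x)
        fused = self.fusion(pyramid, maps)                       # H/4
        d = ag.relu(self.refine_half(
            ag.concat([ag.upsample_nearest2d(fused, 2), half], axis=1)))
        d = ag.relu(self.refine_full(
            ag.concat([ag.upsample_nearest2d(d, 2), full], axis=1)))
        return ag.sigmoid(self.head(d))


class _UNetDown(Module):
    def __init__(self, cin, cout, rng):
        super().__init__()
        self.block = Sequential(
            Conv2d(cin, cout, 3, rng, stride=2), BatchNorm2d(cout), ReLU(),
            Conv2d(cout, cout, 3, rng), BatchNorm2d(cout), ReLU())

    def forward(self, x):
        return self.block(x)


class _UNetUp(Module):
    def __init__(self, cin, cskip, cout, rng):
        super().__init__()
        self.up = UpsampleNearest2d(2)
        self.block = Sequential(
            Conv2d(cin + cskip, cout, 3, rng), BatchNorm2d(cout), ReLU(),
            Conv2d(cout, cout, 3, rng), BatchNorm2d(cout), ReLU())

    def forward(self, x, skip):
        return self.block(ag.concat([self.up(x), skip], axis=1))


class UNetBaseline(Module):
    """Plain 4-level encoder–decoder with skip concatenations."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w = cfg.unet_base_width
        self.stem = Sequential(Conv2d(cfg.in_channels, w, 3, rng),
                               BatchNorm2d(w), ReLU())
        self.down1 = _UNetDown(w, 2 * w, rng)
        self.down2 = _UNetDown(2 * w, 4 * w, rng)
        self.down3 = _UNetDown(4 * w, 8 * w, rng)
        self.down4 = _UNetDown(8 * w, 16 * w, rng)
        self.up1 = _UNetUp(16 * w, 8 * w, 8 * w, rng)
        self.up2 = _UNetUp(8 * w, 4 * w, 4 * w, rng)
        self.up3 = _UNetUp(4 * w, 2 * w, 2 * w, rng)
        self.up4 = _UNetUp(2 * w, w, w, rng)
        self.head = Conv2d(w, cfg.out_channels, 1, rng, padding=0)
        self.head.weight.data *= 0.1

    def forward(self, x) -> Tensor:
        x = ag.as_tensor(x)
        h, w_ = x.shape[-2], x.shape[-1]
        if h % 16 or w_ % 16:
            raise ValueError(f"input size {h}x{w_} must be divisible by 16")
        e0 = self.stem(x)
        e1 = self.down1(e0)
        e2 = self.down2(e1)
        e3 = self.down3(e2)
        e4 = self.down4(e3)
        d = self.up1(e4, e3)
        d = self.up2(d, e2)
        d = self.up3(d, e1)
        d = self.up4(d, e0)
        return ag.sigmoid(self.head(d))


def build_model(cfg: ModelConfig) -> Module:
    if cfg.arch == "mpfnet":
        return MPFNet(cfg)
    if cfg.arch == "unet":
        return UNetBaseline(cfg)
    raise ValueError(f"unknown architecture {cfg.arch!r}")


# ---------------------------------------------------------------------------
# checkpoints: a YAML config next to an npz of weights
# ---------------------------------------------------------------------------

def save_checkpoint(model: Module, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, **state)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(model.cfg.to_dict()))


def load_checkpoint(path) -> Module:
    path = Path(path)
    cfg = ModelConfig.from_dict(yaml.safe_load(path.with_suffix(".yaml").read_text()))
    model = build_model(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as f:
        model.load_state_dict({k: f[k] for k in f.files})
    return model
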