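"""Hierarchical residual-convolution encoder (the CNN branch).

Four stages of residual convolution blocks: stage 1 widens the channel
dimension at full resolution; each later stage begins with a stride-2
convolution so the resolution halves while the channel count grows.  An
extra stride-2 transition sits between stages 1 and 2 so the three
exported feature levels land at 1/4, 1/8 and 1/16 of the input
resolution, where they align with the transformer decoder maps consumed
by the fusion bridge.

Exported pyramid: ``h2`` (H/4, stage-2 width), ``h1`` (H/8, stage-3
width), ``h0`` (H/16, stage-4 width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Conv2d, BatchNorm2d, GroupNorm2d, Sequential
from .nn import autograd as ag


@dataclass
class CnnConfig:
    """Widths and depth of the four stages.

    The channel ladder and blocks-per-stage are free choices exposed here;
    widths must be nondecreasing so the pyramid deepens as it coarsens.
    ``normalization`` is "batch" (default) or "group" for batch-1 work.
    """

    stage_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    blocks_per_stage: int = 2
    normalization: str = "batch"

    def __post_init__(self):
        if len(self.stage_channels) != 4:
            raise ValueError("exactly four stages are required")
        if list(self.stage_channels) != sorted(self.stage_channels):
            raise ValueError("stage channels must be nondecreasing")


def _make_norm(kind: str, channels: int) -> Module:
    if kind == "batch":
        return BatchNorm2d(channels)
    if kind == "group":
        return GroupNorm2d(channels)
    raise ValueError(f"unknown normalization {kind!r}")


class ResidualBlock(Module):
    """conv-norm-act-conv-norm-act plus a (projection) shortcut.

    With the second convolution zeroed the block reduces to its shortcut,
    which is the identity when shapes match.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, stride: int = 1,
                 normalization: str = "batch"):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, rng, stride=stride)
        self.norm1 = _make_norm(normalization, out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, rng)
        self.norm2 = _make_norm(normalization, out_channels)
        if stride != 1 or in_channels != out_channels:
            self.shortcut = Conv2d(in_channels, out_channels, 1, rng,
                                   stride=stride, padding=0)
        else:
            self.shortcut = None

    def forward(self, x):
        y = ag.relu(self.norm1(self.conv1(x)))
        y = ag.relu(self.norm2(self.conv2(y)))
        sc = x if self.shortcut is None else self.shortcut(x)
        return y + sc


class CnnBranch(Module):
    """Four-stage encoder returning the (h2, h1, h0) feature pyramid."""

    def __init__(self, in_channels: int, cfg: CnnConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c1, c2, c3, c4 = cfg.stage_channels
        norm = cfg.normalization

        def stage(cin, cout, stride):
            blocks = [ResidualBlock(cin, cout, rng, stride=stride, normalization=norm)]
            for _ in range(cfg.blocks_per_stage - 1):
                blocks.append(ResidualBlock(cout, cout, rng, normalization=norm))
            return Sequential(*blocks)

        self.stage1 = stage(in_channels, c1, stride=1)     # H
        self.transition = Conv2d(c1, c1, 3, rng, stride=2)  # H/2
        self.stage2 = stage(c1, c2, stride=2)              # H/4
        self.stage3 = stage(c2, c3, stride=2)              # H/8
        self.stage4 = stage(c3, c4, stride=2)              # H/16

    def forward(self, x):
        pyramid, _ = self.forward_with_skips(x)
        return pyramid

    def forward_with_skips(self, x):
        """Pyramid plus the full- and half-resolution encoder features that
        the decoder's upsampling path jump-connects for detail recovery."""
        h, w = x.shape[-2], x.shape[-1]
        if h % 16 or w % 16:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 16; pad the image first")
        full = self.stage1(x)            # H, c1
        half = self.transition(full)     # H/2, c1
        h2 = self.stage2(half)
        h1 = self.stage3(h2)
        h0 = self.stage4(h1)
        return (h2, h1, h0), (full, half)
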