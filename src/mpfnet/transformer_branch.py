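"""Patch-embedding transformer encoder with a progressive-upsampling decoder.

The input stack is cut into non-overlapping M×M patches, each flattened
and linearly embedded to S0 dimensions; a learnable positional table is
added once.  Eight pre-norm transformer layers (multi-head self-attention
and a GELU MLP, both wrapped in residual connections) contextualise the
token sequence.  The decoder reshapes tokens back onto the H/16 grid and
recovers resolution in three steps, emitting maps ``s0`` (H/16), ``s1``
(H/8) and ``s2`` (H/4) whose scales match the CNN feature pyramid.

The layer update is the standard pre-norm form with both residual paths:
``a = z + MSA(LN(z)); z' = a + MLP(LN(a))``.  Dropping the first identity
path would disconnect each layer's output from its input, defeating the
residual design, so the conventional form is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Module, Parameter, Linear, LayerNorm, Conv2d, Dropout,
                 Sequential, GELU)
from .nn import autograd as ag
from .nn.autograd import Tensor


@dataclass
class TransformerConfig:
    """Patch size, embedding width, depth and decoder widths.

    Depth L = 8 is the stated architecture depth; patch size 16, embedding
    width, 4 heads and dropout 0.1 are exposed choices.  ``decoder_channels``
    are the widths (D0, D1, D2) of the three decoder maps.
    """

    image_size: int = 128
    patch_size: int = 16
    embed_dim: int = 256
    depth: int = 8
    n_heads: int = 4
    mlp_ratio: float = 4.0
    dropout: float = 0.1
    decoder_channels: tuple[int, int, int] = (256, 128, 64)

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_tokens(self) -> int:
        return self.grid * self.grid


class PatchEmbed(Module):
    """Flatten M×M×C patches, embed linearly, add learnable positions."""

    def __init__(self, in_channels: int, cfg: TransformerConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.in_channels = in_channels
        patch_dim = cfg.patch_size ** 2 * in_channels
        self.proj = Linear(patch_dim, cfg.embed_dim, rng)
        self.pos = Parameter(rng.normal(0.0, 0.02, (cfg.n_tokens, cfg.embed_dim)))

    def patchify(self, x):
        """(B, C, H, W) -> (B, N, M*M*C); patch vector order is (gh, gw) raster,
        (c, i, j) within a patch."""
        b, c, h, w = x.shape
        m = self.cfg.patch_size
        if h % m or w % m:
            raise ValueError(f"input size {h}x{w} not divisible by patch size {m}")
        gh, gw = h // m, w // m
        y = x.reshape(b, c, gh, m, gw, m)
        y = y.transpose(0, 2, 4, 1, 3, 5)        # B, gh, gw, C, m, m
        return y.reshape(b, gh * gw, c * m * m)

    def forward(self, x):
        tokens = self.proj(self.patchify(x))
        n = tokens.shape[1]
        if n != self.cfg.n_tokens:
            raise ValueError(
                f"got {n} patches but the positional table holds {self.cfg.n_tokens}; "
                "build the model with a matching image_size")
        return tokens + self.pos


class MultiHeadSelfAttention(Module):
    """Scaled dot-product attention over tokens, m heads in parallel.

    Per head, queries/keys/values are d = S/m wide; attention weights are
    row-stochastic softmax(q·kᵀ/√d).  Head outputs are concatenated and
    projected by W_O.
    """

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        s = cfg.embed_dim
        self.n_heads = cfg.n_heads
        self.head_dim = s // cfg.n_heads
        self.w_q = Linear(s, s, rng, bias=False)
        self.w_k = Linear(s, s, rng, bias=False)
        self.w_v = Linear(s, s, rng, bias=False)
        self.w_o = Linear(s, s, rng)
        self._last_attention: np.ndarray | None = None

    def _split(self, t, b, n):
        return t.reshape(b, n, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)

    def forward(self, z, return_attention: bool = False):
        b, n, s = z.shape
        q = self._split(self.w_q(z), b, n)   # B, m, N, d
        k = self._split(self.w_k(z), b, n)
        v = self._split(self.w_v(z), b, n)
        scores = ag.matmul(q, k.transpose(0, 1, 3, 2)) * (self.head_dim ** -0.5)
        attn = ag.softmax(scores, axis=-1)
        if return_attention:
            self._last_attention = attn.data.copy()
        out = ag.matmul(attn, v)             # B, m, N, d
        out = out.transpose(0, 2, 1, 3).reshape(b, n, s)
        return self.w_o(out)


class TransformerLayer(Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        s = cfg.embed_dim
        hidden = int(round(cfg.mlp_ratio * s))
        self.norm1 = LayerNorm(s)
        self.attn = MultiHeadSelfAttention(cfg, rng)
        self.drop1 = Dropout(cfg.dropout, rng)
        self.norm2 = LayerNorm(s)
        self.mlp = Sequential(
            Linear(s, hidden, rng), GELU(), Dropout(cfg.dropout, rng),
            Linear(hidden, s, rng))
        self.drop2 = Dropout(cfg.dropout, rng)

    def forward(self, z):
        a = z + self.drop1(self.attn(self.norm1(z)))
        return a + self.drop2(self.mlp(self.norm2(a)))


class ProgressiveDecoder(Module):
    """Tokens -> (s0 at H/16, s1 at H/8, s2 at H/4) feature maps."""

    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        super().__init__()
        d0, d1, d2 = cfg.decoder_channels
        self.cfg = cfg
        self.conv0 = Conv2d(cfg.embed_dim, d0, 3, rng)
        self.conv1 = Conv2d(d0, d1, 3, rng)
        self.conv2 = Conv2d(d1, d2, 3, rng)

    def forward(self, tokens):
        b, n, s = tokens.shape
        g = int(round(np.sqrt(n)))
        if g * g != n:
            raise ValueError(f"{n} tokens do not form a square grid")
        grid = tokens.reshape(b, g, g, s).transpose(0, 3, 1, 2)
        s0 = ag.relu(self.conv0(grid))
        s1 = ag.relu(self.conv1(ag.upsample_nearest2d(s0, 2)))
        s2 = ag.relu(self.conv2(ag.upsample_nearest2d(s1, 2)))
        return s0, s1, s2


class TransformerBranch(Module):
    """Patch embedding, L transformer layers, progressive decoder."""

    def __init__(self, in_channels: int, cfg: TransformerConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.embed = PatchEmbed(in_channels, cfg, rng)
        self.layers = Sequential(*[TransformerLayer(cfg, rng)
                                   for _ in range(cfg.depth)])
        self.decoder = ProgressiveDecoder(cfg, rng)

    def encode(self, x) -> Tensor:
        return self.layers(self.embed(x))

    def forward(self, x):
        return self.decoder(self.encode(x))
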