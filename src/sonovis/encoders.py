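"""Dual-architecture spatiotemporal feature extraction.

Visual branch: patch embedding, four stages of windowed + shifted-window
self-attention with a hierarchical channel/head schedule (96/192/384/768
channels and 3/6/12/24 heads at full scale; all widths divided by 8 at tiny
scale), followed by a small convolutional decoder that produces the 8x8
feature grid consumed downstream.

Acoustic branch: a convolutional stem over the mel spectrogram, patch
embedding onto an 8x4 time-frequency token grid, sinusoidal temporal
positional encoding, and Transformer stages mirroring the visual depth/width
schedule.

A single shared projection matrix maps both branches into the common width
``d`` so cross-modal attention operates in one aligned subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["EncoderConfig", "FeatureMap", "VisualEncoder", "AcousticEncoder",
           "SharedProjection", "DualEncoder", "fit_frames"]


@dataclass
class EncoderConfig:
    scale: str = "tiny"
    image_size: int = 128
    visual_stage_channels: tuple = (12, 24, 48, 96)
    visual_heads: tuple = (3, 6, 12, 24)
    window: int = 4
    shared_dim: int = 64
    mel_bins: int = 64
    mel_frames: int = 96
    blocks_per_stage: int = 2
    mlp_ratio: float = 2.0

    def __post_init__(self):
        for c, h in zip(self.visual_stage_channels, self.visual_heads):
            if c % h:
                raise ValueError(f"heads ({h}) must divide channels ({c})")
        if self.image_size % 32:
            raise ValueError("image_size must be divisible by 32")
        if self.mel_bins % 8 or self.mel_frames % 4:
            raise ValueError("mel grid must patch onto 8x4 tokens")

    @classmethod
    def tiny(cls, image_size: int = 128) -> "EncoderConfig":
        return cls(scale="tiny", image_size=image_size,
                   visual_stage_channels=(12, 24, 48, 96),
                   visual_heads=(3, 6, 12, 24), shared_dim=64)

    @classmethod
    def full(cls, image_size: int = 256) -> "EncoderConfig":
        return cls(scale="full", image_size=image_size,
                   visual_stage_channels=(96, 192, 384, 768),
                   visual_heads=(3, 6, 12, 24), shared_dim=512)


@dataclass
class FeatureMap:
    """Spatial (visual) or time-frequency (acoustic) grid of activations."""

    grid: Tensor               # (B, H, W, C)
    modality: str

    def __post_init__(self):
        if not np.isfinite(self.grid.data).all():
            raise ValueError("feature map contains non-finite values")

    @property
    def shape(self):
        return self.grid.shape


def fit_frames(melspec: np.ndarray, n_frames: int) -> np.ndarray:
    """Centre-crop or edge-pad a (F, T) spectrogram to exactly n_frames."""
    f, t = melspec.shape
    if t == n_frames:
        return melspec
    if t > n_frames:
        start = (t - n_frames) // 2
        return melspec[:, start:start + n_frames]
    pad = n_frames - t
    return np.pad(melspec, ((0, 0), (pad // 2, pad - pad // 2)), mode="edge")


def _roll_tokens(x: Tensor, shift: int) -> Tensor:
    """Cyclic shift of a (B, H, W, C) token grid along both spatial axes."""
    if shift == 0:
        return x
    h, w = x.shape[1], x.shape[2]
    idx_h = (np.arange(h) + shift) % h
    idx_w = (np.arange(w) + shift) % w
    return x[:, idx_h][:, :, idx_w]


class _WindowBlock(nn.Module):
    """One windowed-attention block: (shifted) W-MSA + MLP, pre-norm residual."""

    def __init__(self, dim: int, heads: int, window: int, shifted: bool,
                 mlp_ratio: float, rng: np.random.Generator):
        super().__init__()
        self.window = window
        self.shifted = shifted
        self.norm1 = nn.LayerNorm(dim)
        self.attn = nn.MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.mlp = nn.Sequential(nn.Linear(dim, hidden, rng), nn.GELU(),
                                 nn.Linear(hidden, dim, rng))

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        win = min(self.window, h, w)
        shift = win // 2 if (self.shifted and win > 1) else 0
        y = self.norm1(x)
        y = _roll_tokens(y, -shift)
        nh, nw = h // win, w // win
        y = (y.reshape(b, nh, win, nw, win, c)
              .transpose((0, 1, 3, 2, 4, 5))
              .reshape(b * nh * nw, win * win, c))
        y = self.attn(y)
        y = (y.reshape(b, nh, nw, win, win, c)
              .transpose((0, 1, 3, 2, 4, 5))
              .reshape(b, h, w, c))
        y = _roll_tokens(y, shift)
        x = x + y
        return x + self.mlp(self.norm2(x))


class VisualEncoder(nn.Module):
    """Hierarchical windowed-attention backbone with convolutional decoder."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        chans = config.visual_stage_channels
        self.patch_embed = nn.Conv2d(3, chans[0], 4, rng, stride=4)
        blocks: list[nn.Module] = []
        merges: list[nn.Module] = []
        for i, (c, hds) in enumerate(zip(chans, config.visual_heads)):
            for j in range(config.blocks_per_stage):
                blocks.append(_WindowBlock(c, hds, config.window,
                                           shifted=(j % 2 == 1),
                                           mlp_ratio=config.mlp_ratio, rng=rng))
            if i < len(chans) - 1:
                merges.append(nn.Conv2d(c, chans[i + 1], 2, rng, stride=2))
        self.blocks = blocks
        self.merges = merges
        # decoder: transposed convs restore the 8x8 grid from the last stage
        last_grid = config.image_size // 32
        n_up = 0
        g = last_grid
        while g < 8:
            g *= 2
            n_up += 1
        if g != 8:
            raise ValueError("image_size must reduce to an 8x8 grid "
                             "(use 64, 128 or 256)")
        self.decoder_ups = [nn.ConvTranspose2d(chans[-1], chans[-1], 3, rng,
                                               stride=2, padding=1,
                                               output_padding=1)
                            for _ in range(n_up)]
        self.decoder_conv = nn.Conv2d(chans[-1], chans[-1], 3, rng,
                                      stride=1, padding=1)

    def forward(self, images: Tensor) -> FeatureMap:
        """images: (B, H, W, 3) in [0, 1] -> feature grid (B, 8, 8, C_last)."""
        if images.shape[1] != self.config.image_size:
            raise ValueError(
                f"expected {self.config.image_size}px input, got {images.shape[1]}")
        if images.dtype != nn.modules.DTYPE and not images.requires_grad:
            images = Tensor(images.data.astype(nn.modules.DTYPE))
        x = images.transpose((0, 3, 1, 2))          # NCHW
        x = self.patch_embed(x).transpose((0, 2, 3, 1))
        per_stage = self.config.blocks_per_stage
        k = 0
        for i in range(len(self.config.visual_stage_channels)):
            for _ in range(per_stage):
                x = self.blocks[k](x)
                k += 1
            if i < len(self.merges):
                x = self.merges[i](x.transpose((0, 3, 1, 2))).transpose((0, 2, 3, 1))
        x = x.transpose((0, 3, 1, 2))
        for up in self.decoder_ups:
            x = up(x).gelu()
        x = self.decoder_conv(x).gelu()
        return FeatureMap(x.transpose((0, 2, 3, 1)), "visual")


def _sinusoidal_encoding(n_time: int, n_freq: int, dim: int) -> np.ndarray:
    """Temporal positional encoding broadcast over the frequency axis."""
    pos = np.arange(n_time)[:, None]
    i = np.arange(dim)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))  # (T, C)
    return np.broadcast_to(pe[None, :, :], (n_freq, n_time, dim)).reshape(
        n_freq * n_time, dim)


class _TransformerBlock(nn.Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = nn.MultiHeadSelfAttention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.mlp = nn.Sequential(nn.Linear(dim, hidden, rng), nn.GELU(),
                                 nn.Linear(hidden, dim, rng))

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class AcousticEncoder(nn.Module):
    """Conv stem + patch Transformer over the mel spectrogram (8x4 tokens)."""

    GRID = (8, 4)  # frequency x time token grid

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        chans = config.visual_stage_channels   # same schedule as visual branch
        gf, gt = self.GRID
        pf = config.mel_bins // gf
        pt = config.mel_frames // gt
        self.stem = nn.Conv2d(1, chans[0], 3, rng, stride=1, padding=1)
        self.patch_embed = nn.Conv2d(chans[0], chans[0], (pf, pt), rng,
                                     stride=(pf, pt))
        self.pos = Tensor((_sinusoidal_encoding(gt, gf, chans[0]) * 0.1
                           ).astype(nn.modules.DTYPE))
        blocks: list[nn.Module] = []
        projs: list[nn.Module] = []
        for i, (c, hds) in enumerate(zip(chans, config.visual_heads)):
            if i > 0:
                projs.append(nn.Linear(chans[i - 1], c, rng))
            for _ in range(config.blocks_per_stage):
                blocks.append(_TransformerBlock(c, hds, config.mlp_ratio, rng))
        self.blocks = blocks
        self.projs = projs

    def forward(self, melspec: Tensor) -> FeatureMap:
        """melspec: (B, F, T) -> feature grid (B, 8, 4, C_last)."""
        if melspec.shape[1:] != (self.config.mel_bins, self.config.mel_frames):
            raise ValueError(
                f"expected ({self.config.mel_bins}, {self.config.mel_frames}) "
                f"spectrogram, got {tuple(melspec.shape[1:])}")
        if melspec.dtype != nn.modules.DTYPE and not melspec.requires_grad:
            melspec = Tensor(melspec.data.astype(nn.modules.DTYPE))
        b = melspec.shape[0]
        gf, gt = self.GRID
        x = melspec.reshape(b, 1, *melspec.shape[1:])
        x = self.stem(x).gelu()
        x = self.patch_embed(x)                       # (B, C, 8, 4)
        x = x.transpose((0, 2, 3, 1)).reshape(b, gf * gt, -1)
        x = x + self.pos
        per_stage = self.config.blocks_per_stage
        k = 0
        for i in range(len(self.config.visual_stage_channels)):
            if i > 0:
                x = self.projs[i - 1](x)
            for _ in range(per_stage):
                x = self.blocks[k](x)
                k += 1
        return FeatureMap(x.reshape(b, gf, gt, -1), "acoustic")


class SharedProjection(nn.Module):
    """One projection matrix Wp applied per position to both modalities."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.proj = nn.Linear(d_in, d_out, rng)

    def forward(self, fmap: FeatureMap) -> FeatureMap:
        return FeatureMap(self.proj(fmap.grid), fmap.modality)


class DualEncoder(nn.Module):
    """Visual + acoustic branches behind the shared projection."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.visual = VisualEncoder(config, rng)
        self.acoustic = AcousticEncoder(config, rng)
        d_in = config.visual_stage_channels[-1]
        self.shared = SharedProjection(d_in, config.shared_dim, rng)

    def encode_visual(self, images: Tensor) -> FeatureMap:
        return self.shared(self.visual(images))

    def encode_acoustic(self, melspecs: Tensor) -> FeatureMap:
        return self.shared(self.acoustic(melspecs))
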