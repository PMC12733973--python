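"""Bidirectional cross-modal attention fusion.

Visual tokens attend over acoustic tokens and vice versa: with shared
projections Wq, Wk, Wv the attention weights are

    alpha_va = softmax(V Wq (A Wk)^T / sqrt(d)),
    alpha_av = softmax(A Wq (V Wk)^T / sqrt(d)),

and the streams are updated as V' = alpha_va (A Wv), A' = alpha_av (V Wv),
each followed by a residual connection and layer normalisation.  Four
interaction layers run at the encoder token resolution with a per-layer
channel schedule (128/256/512/512 at full scale, divided by 8 at tiny
scale); each layer projects the shared width d into its channel width and
back.  The final layer's acoustic-to-visual attention is summed over
acoustic queries to give the attention marginal over visual positions, the
distribution the explanation module aligns against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .encoders import FeatureMap
from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["XAttnConfig", "FusionOutput", "CrossModalFusion",
           "fused_embedding", "attention_marginal"]


@dataclass
class XAttnConfig:
    d: int = 64
    n_layers: int = 4
    layer_channels: tuple = (16, 32, 64, 64)
    # stated per-layer spatial budgets; interaction runs at token resolution
    layer_grids: tuple = ((32, 32), (16, 16), (8, 8), (4, 4))

    def __post_init__(self):
        if self.n_layers != len(self.layer_channels) or \
                self.n_layers != len(self.layer_grids):
            raise ValueError("n_layers must match channel and grid schedules")

    @classmethod
    def tiny(cls) -> "XAttnConfig":
        return cls(d=64, layer_channels=(16, 32, 64, 64))

    @classmethod
    def full(cls) -> "XAttnConfig":
        return cls(d=512, layer_channels=(128, 256, 512, 512))


@dataclass
class FusionOutput:
    """Updated token streams plus the final-layer attention arrays."""

    v_tokens: Tensor           # (B, Nv, d) after the last interaction layer
    a_tokens: Tensor           # (B, Na, d)
    alpha_va: Tensor           # (B, Nv, Na), rows sum to 1
    alpha_av: Tensor           # (B, Na, Nv), rows sum to 1
    v_pre: Tensor              # pre-normalisation V + alpha_va (A Wv)
    a_pre: Tensor
    visual_grid: tuple = (8, 8)


class _InteractionLayer(nn.Module):
    """One bidirectional block; projections shared between the two streams."""

    def __init__(self, d: int, channels: int, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        self.in_proj = nn.Linear(d, channels, rng)
        self.wq = nn.Linear(channels, channels, rng, bias=False)
        self.wk = nn.Linear(channels, channels, rng, bias=False)
        self.wv = nn.Linear(channels, channels, rng, bias=False)
        self.out_proj = nn.Linear(channels, d, rng)
        self.norm = nn.LayerNorm(d)

    def attend(self, q_tokens: Tensor, kv_tokens: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (attention weights, attended values) in layer channels."""
        scale = self.channels ** -0.5
        logits = self.wq(q_tokens) @ self.wk(kv_tokens).transpose((0, 2, 1)) * scale
        alpha = F.softmax(logits, axis=-1)
        return alpha, alpha @ self.wv(kv_tokens)

    def forward(self, v: Tensor, a: Tensor):
        vc, ac = self.in_proj(v), self.in_proj(a)
        alpha_va, v_ctx = self.attend(vc, ac)
        alpha_av, a_ctx = self.attend(ac, vc)
        v_pre = v + self.out_proj(v_ctx)
        a_pre = a + self.out_proj(a_ctx)
        return self.norm(v_pre), self.norm(a_pre), alpha_va, alpha_av, v_pre, a_pre


class CrossModalFusion(nn.Module):
    """Stack of bidirectional interaction layers over projected feature grids."""

    def __init__(self, config: XAttnConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.layers = [_InteractionLayer(config.d, c, rng)
                       for c in config.layer_channels]

    def forward(self, fv: FeatureMap, fa: FeatureMap) -> FusionOutput:
        if fv.shape[-1] != self.config.d or fa.shape[-1] != self.config.d:
            raise ValueError(
                f"token width must be {self.config.d}, got "
                f"{fv.shape[-1]} / {fa.shape[-1]}")
        b, hv, wv, d = fv.shape
        _, ha, wa, _ = fa.shape
        v = fv.grid.reshape(b, hv * wv, d)
        a = fa.grid.reshape(b, ha * wa, d)
        alpha_va = alpha_av = v_pre = a_pre = None
        for layer in self.layers:
            v, a, alpha_va, alpha_av, v_pre, a_pre = layer(v, a)
        return FusionOutput(v, a, alpha_va, alpha_av, v_pre, a_pre,
                            visual_grid=(hv, wv))


def fused_embedding(out: FusionOutput) -> tuple[Tensor, Tensor]:
    """Mean-pool both streams over token positions for the contrastive head."""
    return out.v_tokens.mean(axis=1), out.a_tokens.mean(axis=1)


def attention_marginal(out: FusionOutput, out_size: int = 64,
                       batch_index: int | None = None) -> Tensor:
    """Spatial distribution of acoustic-to-visual attention mass.

    Sums the final layer's alpha_av over acoustic query positions, reshapes
    to the visual grid, normalises to sum 1, bilinearly upsamples to
    ``out_size`` and renormalises.  Stays inside the autodiff graph so the
    explanation-alignment loss can steer the attention.
    """
    mass = out.alpha_av.sum(axis=1)                       # (B, Nv)
    mass = mass / mass.sum(axis=-1, keepdims=True)
    h, w = out.visual_grid
    grid = mass.reshape(mass.shape[0], h, w)
    if batch_index is not None:
        grid = grid[batch_index]
    up = F.resize_bilinear(grid, (out_size, out_size))
    up = up.maximum(0.0)
    if up.ndim == 2:
        return up / up.sum()
    flat_sum = up.sum(axis=(-2, -1), keepdims=True)
    return up / flat_sum
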