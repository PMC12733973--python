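"""Dual-modality explainability: saliency, interpreter heads, gated fusion.

Visual saliency comes from class-activation mapping on the projected visual
feature grid: plain Grad-CAM (channel weights are spatially averaged
gradients) and Grad-CAM++ (pixel-level weighting from the second/third
derivative ratio, evaluated through the exp-logit closed form so only
first-order gradients are required).  Acoustic saliency uses integrated
gradients between the mel spectrogram and a baseline, with the completeness
residual reported.  Per-modality maps are min-max normalised onto a common
64x64 grid and fused by a learned pixel-wise gate G in [0, 1]:

    Hc = G * Hv + (1 - G) * Ha,

which keeps the fused map inside the pointwise envelope of the two inputs.
Lightweight interpreter heads (1x1 reduction + transposed-conv upsampling)
are trained to regress the gradient-based maps, giving a cheap
amortised explanation path.  The explanation loss combines total-variation
smoothness, KL alignment between the fused map and the cross-modal
attention marginal, and a class-gating penalty on background activations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .encoders import FeatureMap
from .nn import functional as F
from .nn.modules import DTYPE
from .nn.tensor import Tensor, concat

logger = logging.getLogger(__name__)

__all__ = ["Heatmap", "XaiConfig", "normalize_map", "gradcam", "gradcam_pp",
           "integrated_gradients", "InterpreterHead", "GateNet",
           "gated_fuse", "fixed_beta_fuse", "loss_xai", "mask_to_feature_grid",
           "visual_saliency", "acoustic_saliency", "ExplainModule"]

MAP_SIZE = 64


@dataclass
class Heatmap:
    grid: np.ndarray           # (64, 64) non-negative
    modality: str              # visual | acoustic | fused
    class_id: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.shape != (MAP_SIZE, MAP_SIZE):
            raise ValueError(f"heatmap must be {MAP_SIZE}x{MAP_SIZE}")
        if self.grid.min() < 0:
            raise ValueError("heatmap values must be non-negative")


@dataclass
class XaiConfig:
    ig_steps: int = 32
    ig_baseline: str = "zeros"         # zeros | mean
    gate_hidden: int = 16
    mu_tv: float = 0.1                 # weight of the smoothness term
    mu_align: float = 0.1              # weight of the KL alignment term
    mu_gate: float = 0.01              # weight of the class-gating term
    tv_mode: str = "anisotropic"       # anisotropic | isotropic

    def __post_init__(self):
        if self.ig_steps < 8:
            raise ValueError("ig_steps must be >= 8")
        if self.ig_baseline not in ("zeros", "mean"):
            raise ValueError("ig_baseline must be 'zeros' or 'mean'")
        if min(self.mu_tv, self.mu_align, self.mu_gate) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.tv_mode not in ("anisotropic", "isotropic"):
            raise ValueError("tv_mode must be 'anisotropic' or 'isotropic'")


def normalize_map(grid: np.ndarray) -> np.ndarray:
    """Min-max normalisation to [0, 1]; a constant map becomes all zeros."""
    lo, hi = float(grid.min()), float(grid.max())
    if hi - lo < 1e-12:
        return np.zeros_like(grid, dtype=float)
    return (grid - lo) / (hi - lo)


def _resize64(grid: np.ndarray) -> np.ndarray:
    ry = F.resize_matrix(MAP_SIZE, grid.shape[0])
    rx = F.resize_matrix(MAP_SIZE, grid.shape[1])
    return ry @ grid @ rx.T


# ---------------------------------------------------------------------------
# gradient-based saliency (pure-array core operations)
# ---------------------------------------------------------------------------

def gradcam(activations: np.ndarray, grads: np.ndarray,
            class_id: int = 0) -> Heatmap:
    """Grad-CAM: channel weights are spatial means of the gradients.

    activations, grads: (H, W, C) for one sample.  All-zero gradients yield
    an all-zero map with a logged warning.
    """
    if activations.shape != grads.shape:
        raise ValueError("activation/gradient shapes differ")
    if not np.any(grads):
        logger.warning("all-zero gradients: returning an empty saliency map")
        return Heatmap(np.zeros((MAP_SIZE, MAP_SIZE)), "visual", class_id)
    alpha = grads.mean(axis=(0, 1))                    # (C,)
    cam = np.maximum((activations * alpha).sum(axis=-1), 0.0)
    return Heatmap(normalize_map(_resize64(cam)), "visual", class_id)


def gradcam_weights(grads: np.ndarray) -> np.ndarray:
    """Grad-CAM channel weights alpha_k = (1/Z) sum_ij dY/dA_ijk."""
    return grads.mean(axis=(0, 1))


def gradcam_pp(activations: np.ndarray, grads: np.ndarray,
               class_id: int = 0, verbatim: bool = False) -> Heatmap:
    """Grad-CAM++ via the exp-logit closed form.

    For y = exp(s) with s locally linear in A, the second and third
    derivatives are g^2 e^s and g^3 e^s (g = ds/dA), so the pixel weights
    reduce to g^2 / (2 g^2 + sum_ij A g^3); channel weights aggregate the
    pixel weights gated by ReLU(g).  ``verbatim`` evaluates the printed
    channel-level ratio without the ReLU gating.
    """
    if activations.shape != grads.shape:
        raise ValueError("activation/gradient shapes differ")
    g = grads
    g2 = g * g
    g3 = g2 * g
    if verbatim:
        num = g2.sum(axis=(0, 1))
        den = 2.0 * g2.sum(axis=(0, 1)) + (activations * g3).sum(axis=(0, 1))
        alpha = num / (den + 1e-8)
        cam = np.maximum((activations * alpha).sum(axis=-1), 0.0)
    else:
        denom = 2.0 * g2 + (activations * g3).sum(axis=(0, 1), keepdims=True)
        pixel_w = np.where(np.abs(denom) < 1e-8, 0.0, g2 / (denom + 1e-8))
        alpha = (pixel_w * np.maximum(g, 0.0)).sum(axis=(0, 1))
        cam = np.maximum((activations * alpha).sum(axis=-1), 0.0)
    return Heatmap(normalize_map(_resize64(cam)), "visual", class_id)


def integrated_gradients(model_fn, melspec: np.ndarray,
                         baseline: np.ndarray | None, class_id: int,
                         ig_steps: int = 32
                         ) -> tuple[Heatmap, np.ndarray, float]:
    """Integrated gradients along the straight path baseline -> input.

    ``model_fn`` maps a (F, T) Tensor to the scalar class logit.  Uses the
    midpoint Riemann rule.  Returns the 64x64 heatmap (absolute attributions,
    min-max normalised), the raw signed attribution grid, and the
    completeness residual |sum(attr) - (y(S) - y(S'))|.
    """
    s = np.asarray(melspec, dtype=DTYPE)
    sp = np.zeros_like(s) if baseline is None else np.asarray(baseline, DTYPE)
    if s.shape != sp.shape:
        raise ValueError("input and baseline shapes differ")
    diff = s - sp
    grad_sum = np.zeros_like(s, dtype=np.float64)
    for m in range(ig_steps):
        t = (m + 0.5) / ig_steps
        point = Tensor((sp + t * diff).astype(DTYPE), requires_grad=True)
        logit = model_fn(point)
        logit.backward()
        grad_sum += point.grad.astype(np.float64)
    attributions = diff.astype(np.float64) * grad_sum / ig_steps
    with nn.no_grad():
        y1 = model_fn(Tensor(s)).item()
        y0 = model_fn(Tensor(sp)).item()
    residual = abs(attributions.sum() - (y1 - y0))
    heat = Heatmap(normalize_map(_resize64(np.abs(attributions))),
                   "acoustic", class_id)
    return heat, attributions, residual


# ---------------------------------------------------------------------------
# interpreter heads and gated fusion
# ---------------------------------------------------------------------------

class InterpreterHead(nn.Module):
    """1x1 channel reduction + three stride-2 transposed convolutions.

    The visual path upsamples 8x8 -> 64x64 directly; the acoustic 8x4 grid
    reaches 64x32 after the deconvolution stack and is brought to 64x64 by a
    bilinear width resize (three symmetric stride-2 deconvolutions cannot
    produce a square map from a non-square grid).
    """

    def __init__(self, c_in: int, rng: np.random.Generator, c_mid: int = 16):
        super().__init__()
        self.reduce = nn.Conv2d(c_in, c_mid, 1, rng)
        self.up1 = nn.ConvTranspose2d(c_mid, c_mid // 2, 4, rng, stride=2,
                                      padding=1)
        self.up2 = nn.ConvTranspose2d(c_mid // 2, max(c_mid // 4, 1), 4, rng,
                                      stride=2, padding=1)
        self.up3 = nn.ConvTranspose2d(max(c_mid // 4, 1), 1, 4, rng, stride=2,
                                      padding=1)

    def forward(self, fmap: FeatureMap) -> Tensor:
        grid = fmap.grid
        if grid.shape[1] != 8 or grid.shape[2] not in (4, 8):
            raise ValueError("interpreter head expects an 8x8 or 8x4 grid")
        x = grid.transpose((0, 3, 1, 2))
        x = self.reduce(x).gelu()
        x = self.up1(x).gelu()
        x = self.up2(x).gelu()
        x = self.up3(x)                      # (B, 1, 64, 64) or (B, 1, 64, 32)
        x = x.reshape(x.shape[0], x.shape[2], x.shape[3])
        if x.shape[-1] != MAP_SIZE:
            x = F.resize_bilinear(x, (MAP_SIZE, MAP_SIZE))
        return x


class GateNet(nn.Module):
    """Pixel-wise gate from the stacked heatmaps: 1x1 convs 2 -> hidden -> 1."""

    def __init__(self, rng: np.random.Generator, hidden: int = 16):
        super().__init__()
        self.conv1 = nn.Conv2d(2, hidden, 1, rng)
        self.conv2 = nn.Conv2d(hidden, 1, 1, rng)

    def forward(self, hv: Tensor, ha: Tensor) -> Tensor:
        """hv, ha: (B, 64, 64) normalised maps -> gate (B, 64, 64) in [0, 1]."""
        stacked = concat([hv.reshape(hv.shape[0], 1, *hv.shape[1:]),
                          ha.reshape(ha.shape[0], 1, *ha.shape[1:])], axis=1)
        return self.conv2(self.conv1(stacked).gelu()).sigmoid().reshape(hv.shape)


def gated_fuse(hv: Heatmap, ha: Heatmap, gate: GateNet
               ) -> tuple[Heatmap, np.ndarray]:
    """Hc = G * Hv + (1 - G) * Ha with a learned pixel-wise gate.

    Unnormalised inputs are min-max normalised first (with a warning), so the
    convex combination keeps every pixel inside [min, max] of the two maps.
    """
    grids = []
    for h in (hv, ha):
        g = h.grid
        if g.max() > 1.0 + 1e-9:
            logger.warning("heatmap not normalised; applying min-max")
            g = normalize_map(g)
        grids.append(g.astype(DTYPE))
    with nn.no_grad():
        hv_t = Tensor(grids[0][None])
        ha_t = Tensor(grids[1][None])
        g = gate(hv_t, ha_t).data[0]
        fused = g * grids[0] + (1.0 - g) * grids[1]
    return Heatmap(fused.astype(float), "fused", hv.class_id), g.astype(float)


def fixed_beta_fuse(lv: Heatmap, la: Heatmap, beta: float) -> Heatmap:
    """Non-learned baseline fusion: beta * Lv + (1 - beta) * La."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    return Heatmap(beta * lv.grid + (1.0 - beta) * la.grid, "fused",
                   lv.class_id)


# ---------------------------------------------------------------------------
# explanation losses
# ---------------------------------------------------------------------------

def _softmax_flat(x: Tensor) -> Tensor:
    flat = x.reshape(x.size)
    return F.softmax(flat, axis=-1)


def total_variation(h: Tensor, mode: str = "anisotropic") -> Tensor:
    """Sum of absolute (or isotropic L2) forward differences."""
    dy = h[1:, :] - h[:-1, :]
    dx = h[:, 1:] - h[:, :-1]
    if mode == "isotropic":
        dy2 = (dy[:, :-1] * dy[:, :-1])
        dx2 = (dx[:-1, :] * dx[:-1, :])
        return ((dy2 + dx2 + 1e-16).sqrt()).sum()
    return dy.abs().sum() + dx.abs().sum()


def mask_to_feature_grid(mask: np.ndarray, grid_hw: tuple) -> np.ndarray:
    """Downsample a pixel mask to the feature grid (block mean > 0.5)."""
    h, w = grid_hw
    ry = F.resize_matrix(h, mask.shape[0])
    rx = F.resize_matrix(w, mask.shape[1])
    down = ry @ mask.astype(float) @ rx.T
    return (down > 0.5).astype(float)


def loss_xai(hc: Tensor, mc: Tensor, features: Tensor, class_mask: np.ndarray,
             config: XaiConfig) -> tuple[Tensor, dict]:
    """mu1 * L_tv + mu2 * KL(softmax Hc || softmax Mc) + mu3 * R_gate.

    ``hc`` and ``mc`` are (64, 64) maps; ``class_mask`` gates the feature
    grid (broadcastable to ``features``).  Returns the total and the three
    components.
    """
    h_tilde = _softmax_flat(hc)
    m_tilde = _softmax_flat(mc)
    l_align = F.kl_divergence(h_tilde, m_tilde)
    l_tv = total_variation(hc, config.tv_mode)
    mask = Tensor(np.asarray(class_mask, dtype=features.dtype))
    gated = features - features * mask
    r_gate = (gated * gated).mean()
    total = l_tv * config.mu_tv + l_align * config.mu_align + \
        r_gate * config.mu_gate
    return total, {"tv": float(l_tv.data), "align": float(l_align.data),
                   "gate": float(r_gate.data)}


# ---------------------------------------------------------------------------
# model-level convenience paths
# ---------------------------------------------------------------------------

def visual_saliency(model, images: Tensor, mels: Tensor, class_id: int,
                    batch_index: int = 0, method: str = "gradcam_pp"
                    ) -> Heatmap:
    """Run the classifier and produce the visual class-activation map."""
    model.zero_grad()
    out = model(images, mels)
    logit = out.logits[batch_index, class_id]
    logit.backward()
    acts = out.fv.grid.data[batch_index]
    grads = out.fv.grid.grad[batch_index]
    model.zero_grad()
    fn = gradcam_pp if method == "gradcam_pp" else gradcam
    return fn(acts.astype(np.float64), grads.astype(np.float64), class_id)


def acoustic_saliency(model, images: Tensor, mels: Tensor, class_id: int,
                      batch_index: int = 0, config: XaiConfig | None = None
                      ) -> tuple[Heatmap, float]:
    """Integrated-gradients heatmap for one sample's mel spectrogram."""
    config = config or XaiConfig()
    mel = mels.data[batch_index]
    baseline = None if config.ig_baseline == "zeros" else \
        np.full_like(mel, mel.mean())
    img_slice = None
    if images is not None:
        img_slice = Tensor(images.data[batch_index:batch_index + 1])

    def model_fn(mel_point: Tensor) -> Tensor:
        model.zero_grad()
        out = model(img_slice,
                    mel_point.reshape(1, *mel_point.shape))
        return out.logits[0, class_id]

    heat, _, residual = integrated_gradients(model_fn, mel, baseline,
                                             class_id, config.ig_steps)
    model.zero_grad()
    return heat, residual


class ExplainModule(nn.Module):
    """Trainable explanation components: two interpreter heads and the gate."""

    def __init__(self, d: int, rng: np.random.Generator, c_mid: int = 16,
                 gate_hidden: int = 16):
        super().__init__()
        self.interp_visual = InterpreterHead(d, rng, c_mid)
        self.interp_acoustic = InterpreterHead(d, rng, c_mid)
        self.gate = GateNet(rng, gate_hidden)
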