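"""The full audio-visual species classifier.

Assembly: dual encoders -> shared projection -> bidirectional cross-modal
attention -> mean-pooled stream embeddings -> classification head, with the
contrastive projection head attached to the pooled embeddings.  Ablation
switches cover the study variants: fusion off (concatenation of pooled
streams without interaction), and unimodal operation (visual- or
acoustic-only classification).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .contrast import ContrastConfig, ProjectionHead
from .encoders import DualEncoder, EncoderConfig, FeatureMap, fit_frames
from .nn.modules import DTYPE
from .nn.tensor import Tensor, concat
from .xfuse import CrossModalFusion, FusionOutput, XAttnConfig, fused_embedding

__all__ = ["ModelConfig", "ModelOutput", "MultimodalClassifier",
           "make_input_tensors", "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    n_classes: int = 3
    modality: str = "multimodal"       # multimodal | visual | acoustic
    use_fusion: bool = True            # cross-modal attention vs concatenation
    encoder: EncoderConfig = field(default_factory=EncoderConfig.tiny)
    fusion: XAttnConfig = field(default_factory=XAttnConfig.tiny)
    contrast: ContrastConfig = field(default_factory=ContrastConfig)

    def __post_init__(self):
        if self.modality not in ("multimodal", "visual", "acoustic"):
            raise ValueError("modality must be multimodal, visual or acoustic")
        if self.encoder.shared_dim != self.fusion.d:
            raise ValueError("encoder shared_dim must match fusion width")

    def to_json(self) -> str:
        return json.dumps({
            "n_classes": self.n_classes,
            "modality": self.modality,
            "use_fusion": self.use_fusion,
            "encoder": self.encoder.__dict__,
            "fusion": {"d": self.fusion.d, "n_layers": self.fusion.n_layers,
                       "layer_channels": list(self.fusion.layer_channels),
                       "layer_grids": [list(g) for g in self.fusion.layer_grids]},
            "contrast": self.contrast.__dict__,
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        doc = json.loads(text)
        enc = doc["encoder"]
        enc["visual_stage_channels"] = tuple(enc["visual_stage_channels"])
        enc["visual_heads"] = tuple(enc["visual_heads"])
        fus = doc["fusion"]
        return cls(n_classes=doc["n_classes"], modality=doc["modality"],
                   use_fusion=doc["use_fusion"],
                   encoder=EncoderConfig(**enc),
                   fusion=XAttnConfig(d=fus["d"], n_layers=fus["n_layers"],
                                      layer_channels=tuple(fus["layer_channels"]),
                                      layer_grids=tuple(tuple(g) for g in
                                                        fus["layer_grids"])),
                   contrast=ContrastConfig(**doc["contrast"]))


@dataclass
class ModelOutput:
    logits: Tensor
    fv: FeatureMap | None          # projected visual features (B, 8, 8, d)
    fa: FeatureMap | None
    fusion: FusionOutput | None
    v_pool: Tensor | None          # pooled stream embeddings (B, d)
    a_pool: Tensor | None


class MultimodalClassifier(nn.Module):
    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.dual = DualEncoder(config.encoder, rng)
        d = config.encoder.shared_dim
        if config.modality == "multimodal" and config.use_fusion:
            self.fusion = CrossModalFusion(config.fusion, rng)
        head_in = 2 * d if config.modality == "multimodal" else d
        self.classifier = nn.Sequential(
            nn.Linear(head_in, d, rng), nn.GELU(),
            nn.Linear(d, config.n_classes, rng))
        self.contrast_head = ProjectionHead(d, config.contrast, rng)

    def forward(self, images: Tensor | None, mels: Tensor | None) -> ModelOutput:
        cfg = self.config
        fv = fa = fusion_out = v_pool = a_pool = None
        if cfg.modality in ("multimodal", "visual"):
            fv = self.dual.encode_visual(images)
        if cfg.modality in ("multimodal", "acoustic"):
            fa = self.dual.encode_acoustic(mels)
        if cfg.modality == "visual":
            v_pool = fv.grid.mean(axis=(1, 2))
            logits = self.classifier(v_pool)
        elif cfg.modality == "acoustic":
            a_pool = fa.grid.mean(axis=(1, 2))
            logits = self.classifier(a_pool)
        elif cfg.use_fusion:
            fusion_out = self.fusion(fv, fa)
            v_pool, a_pool = fused_embedding(fusion_out)
            logits = self.classifier(concat([v_pool, a_pool], axis=-1))
        else:
            v_pool = fv.grid.mean(axis=(1, 2))
            a_pool = fa.grid.mean(axis=(1, 2))
            logits = self.classifier(concat([v_pool, a_pool], axis=-1))
        return ModelOutput(logits, fv, fa, fusion_out, v_pool, a_pool)


def make_input_tensors(pairs, encoder: EncoderConfig,
                       requires_grad: bool = False
                       ) -> tuple[Tensor, Tensor, np.ndarray]:
    """Stack aligned pairs into model input tensors.

    Images are shifted to [-1, 1]; spectrograms are standardised per sample
    and fitted to the configured frame count.
    """
    imgs = np.stack([(p.image.astype(DTYPE) - 0.5) * 2.0 for p in pairs])
    mels = []
    for p in pairs:
        m = fit_frames(p.melspec, encoder.mel_frames).astype(DTYPE)
        mels.append((m - m.mean()) / (m.std() + 1e-6))
    labels = np.array([p.label for p in pairs], dtype=int)
    return (Tensor(imgs, requires_grad=requires_grad),
            Tensor(np.stack(mels), requires_grad=requires_grad), labels)


def save_checkpoint(path: str | Path, model: MultimodalClassifier,
                    extra: dict | None = None):
    """Single-file archive: parameters + embedded config (+ optional extras)."""
    payload = {f"param.{k}": v for k, v in model.state_dict().items()}
    payload["config_json"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8)
    if extra:
        for k, v in extra.items():
            payload[f"extra.{k}"] = np.asarray(v)
    np.savez(str(path), **payload)


def load_checkpoint(path: str | Path,
                    rng: np.random.Generator | None = None
                    ) -> tuple[MultimodalClassifier, dict]:
    with np.load(str(path)) as archive:
        config = ModelConfig.from_json(bytes(archive["config_json"]).decode())
        model = MultimodalClassifier(config, rng or np.random.default_rng(0))
        state = {k[len("param."):]: archive[k] for k in archive.files
                 if k.startswith("param.")}
        model.load_state_dict(state)
        extra = {k[len("extra."):]: archive[k] for k in archive.files
                 if k.startswith("extra.")}
    return model, extra
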