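"""Cross-species contrastive learning.

A shared projection head maps pooled visual/acoustic features into a unit
sphere; the joint embedding of a pair is the normalised mean of its two
modality embeddings.  Positives are other samples of the same species;
negatives are different species ranked by current cosine similarity (hard
negatives first), with designated look-alike species guaranteed a slot when
present in the batch.  The default losses are the standard forms consistent
with the intended optimum (intra-class compact, inter-class separated):

    L_cs      = mean over (anchor, positive) of
                -log exp(s_ip / tau) / (exp(s_ip / tau) + sum_n exp(s_in / tau))
    L_margin  = mean over triplets of max(0, delta + d_ip^2 - d_in^2)
    L_total   = L_cls + lambda1 * L_cs + lambda2 * L_margin

``verbatim=True`` evaluates the printed variants of the contrastive and
margin terms instead (positive log-ratio without the positive term in the
denominator; margin with the distance signs exchanged); they are retained
for comparison only, since their minima contradict the intended geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

logger = logging.getLogger(__name__)

__all__ = ["ContrastConfig", "EmbeddingBatch", "ProjectionHead",
           "project_joint", "build_pairs", "loss_infonce", "loss_margin",
           "loss_total"]


@dataclass
class ContrastConfig:
    embed_dim: int = 32          # 256 at full scale
    head_hidden: int = 64        # 512 at full scale
    temperature: float = 0.07
    margin: float = 0.2
    lambda_contrast: float = 0.5   # weight of L_cs in the total loss
    lambda_margin: float = 0.1     # weight of L_margin
    top_k_negatives: int | None = None   # None: use all different-class samples

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.lambda_contrast < 0 or self.lambda_margin < 0:
            raise ValueError("loss weights must be non-negative")

    @classmethod
    def full(cls) -> "ContrastConfig":
        return cls(embed_dim=256, head_hidden=512)


@dataclass
class EmbeddingBatch:
    zm: Tensor                 # (N, d) unit-norm joint embeddings
    labels: np.ndarray
    similarity: np.ndarray     # (N, N) cosine similarity, diagonal excluded
    positives: list            # per anchor: indices of same-class samples
    negatives: list            # per anchor: hard-negative indices, ranked


class ProjectionHead(nn.Module):
    """Two-layer head (hidden width then embed width) with L2 normalisation."""

    def __init__(self, d_in: int, config: ContrastConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.fc1 = nn.Linear(d_in, config.head_hidden, rng)
        self.fc2 = nn.Linear(config.head_hidden, config.embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return F.l2_normalize(self.fc2(self.fc1(x).gelu()), axis=-1)


def project_joint(zv_raw: Tensor, za_raw: Tensor,
                  head: ProjectionHead) -> tuple[Tensor, Tensor, Tensor]:
    """Project both modalities through the shared head; join by normalised mean."""
    if zv_raw.shape != za_raw.shape:
        raise ValueError("modality feature widths differ")
    zv = head(zv_raw)
    za = head(za_raw)
    zm = F.l2_normalize((zv + za) * 0.5, axis=-1)
    return zv, za, zm


def build_pairs(zm: Tensor, labels: np.ndarray,
                similar_to: dict | None = None,
                top_k: int | None = None) -> EmbeddingBatch:
    """Positive/negative index sets per anchor from the similarity matrix.

    Negatives are ranked by descending cosine similarity (hardest first) and
    truncated to ``top_k``; a sample of the anchor's designated look-alike
    class is always kept when one is present in the batch.
    """
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("batch holds a single class: no negatives available")
    sims = zm.data @ zm.data.T
    n = labels.size
    positives, negatives = [], []
    for i in range(n):
        pos = [j for j in range(n) if j != i and labels[j] == labels[i]]
        neg = [j for j in range(n) if labels[j] != labels[i]]
        neg.sort(key=lambda j: -sims[i, j])
        if top_k is not None and len(neg) > top_k:
            kept = neg[:top_k]
            twin = None if similar_to is None else similar_to.get(int(labels[i]))
            if twin is not None and not any(labels[j] == twin for j in kept):
                twin_js = [j for j in neg if labels[j] == twin]
                if twin_js:
                    kept[-1] = twin_js[0]
            neg = kept
        positives.append(pos)
        negatives.append(neg)
    return EmbeddingBatch(zm, labels, sims, positives, negatives)


def loss_infonce(batch: EmbeddingBatch, config: ContrastConfig,
                 verbatim: bool = False) -> Tensor:
    """Contrastive loss over the batch's pairs (see module docstring).

    Anchors without a positive are excluded from the average with a logged
    warning.
    """
    inv_t = 1.0 / config.temperature
    sims = batch.zm @ batch.zm.transpose((1, 0))
    exp_s = (sims * inv_t).exp()
    n = batch.labels.size
    neg_mask = np.zeros((n, n), dtype=batch.zm.dtype)
    for i, neg in enumerate(batch.negatives):
        neg_mask[i, neg] = 1.0
    denom_neg = (exp_s * Tensor(neg_mask)).sum(axis=1)

    anchor_idx, pos_idx = [], []
    for i, pos in enumerate(batch.positives):
        if not pos:
            logger.warning("anchor %d has no positive; excluded from loss", i)
            continue
        for p in pos:
            anchor_idx.append(i)
            pos_idx.append(p)
    if not anchor_idx:
        raise ValueError("no anchor has a positive partner")
    ai = np.asarray(anchor_idx)
    pi = np.asarray(pos_idx)
    e_pos = exp_s[ai, pi]
    if verbatim:
        # printed form: positive log-ratio, negatives-only denominator
        return (e_pos.log() - denom_neg[ai].log()).mean()
    return -((e_pos / (e_pos + denom_neg[ai])).log()).mean()


def loss_margin(batch: EmbeddingBatch, config: ContrastConfig,
                verbatim: bool = False) -> Tensor:
    """Margin loss over all (anchor, positive, negative) triplets."""
    sims = batch.zm @ batch.zm.transpose((1, 0))
    sq_dist = (sims * -2.0) + 2.0          # ||zi - zj||^2 on the unit sphere
    ai, pi, ni = [], [], []
    for i, pos in enumerate(batch.positives):
        if not pos:
            logger.warning("anchor %d has no positive; excluded from loss", i)
            continue
        for p in pos:
            for ng in batch.negatives[i]:
                ai.append(i)
                pi.append(p)
                ni.append(ng)
    if not ai:
        raise ValueError("no triplets available")
    d_pos = sq_dist[np.asarray(ai), np.asarray(pi)]
    d_neg = sq_dist[np.asarray(ai), np.asarray(ni)]
    if verbatim:
        # printed variant: signs of the two distances exchanged
        return (config.margin - d_pos + d_neg).maximum(0.0).mean()
    return (d_pos - d_neg + config.margin).maximum(0.0).mean()


def loss_total(l_cls: Tensor, l_cs: Tensor, l_margin: Tensor,
               config: ContrastConfig) -> Tensor:
    """L_total = L_cls + lambda1 L_cs + lambda2 L_margin; aborts on NaN."""
    for name, term in (("classification", l_cls), ("contrastive", l_cs),
                       ("margin", l_margin)):
        if not np.isfinite(term.data).all():
            raise FloatingPointError(f"{name} loss is not finite")
    return l_cls + l_cs * config.lambda_contrast + l_margin * config.lambda_margin
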