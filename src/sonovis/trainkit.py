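"""Training loop, schedule, evaluation metrics, SNR robustness harness.

The joint objective optimised here is

    L = L_cls + lambda1 L_cs + lambda2 L_margin + L_xai,

with AdamW (weight decay 0.05, betas 0.9/0.999), a cosine-annealed learning
rate, a 70/15/15 split (or k-fold cross-validation) and early stopping on
validation accuracy.  The explanation loss is computed on a subsample of
each scheduled batch: gradient-based saliency maps are produced in a side
pass and treated as fixed targets, so their gradients steer the gate, the
attention marginal and (through the class-gating term) the backbone, and
the interpreter heads are regressed onto them.

The SNR harness corrupts the acoustic modality with energy-normalised noise
profiles (Gaussian, wind-like low-band, rustle-like mid-band, off-frame
insect harmonics) scaled to hit an exact target signal-to-noise ratio.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from . import dsp, nn
from .contrast import (ContrastConfig, EmbeddingBatch, build_pairs,
                       loss_infonce, loss_margin, loss_total)
from .explain import (ExplainModule, XaiConfig, acoustic_saliency, loss_xai,
                      mask_to_feature_grid, visual_saliency)
from .model import (ModelConfig, MultimodalClassifier, make_input_tensors,
                    save_checkpoint)
from .nn import functional as F
from .nn.modules import DTYPE
from .nn.tensor import Tensor, concat
from .xfuse import attention_marginal

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "MetricsReport", "SNRSpec", "cosine_lr",
           "compute_metrics", "mix_at_snr", "make_noise", "train",
           "TrainResult", "evaluate", "kfold", "split_dataset"]


@dataclass
class TrainConfig:
    batch_size: int = 8
    epochs: int = 30
    eta_max: float = 5e-4          # tiny-scale peak learning rate
    eta_min: float = 1e-5
    weight_decay: float = 0.05
    betas: tuple = (0.9, 0.999)
    split: tuple = (0.7, 0.15, 0.15)
    folds: int = 5
    patience: int = 10             # early-stopping patience, epochs
    seed: int = 0
    use_contrast: bool = True
    use_xai: bool = True
    # acoustic noise augmentation: per-sample SNR drawn uniformly from this
    # range (dB); None disables it
    noise_snr_range: tuple | None = None
    noise_kind: str = "gaussian"
    sample_rate: float = 22050.0
    xai_every: int = 4             # explanation loss every k-th step
    xai_samples: int = 1           # saliency targets per scheduled batch
    ig_steps_train: int = 8

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.eta_min > self.eta_max:
            raise ValueError("eta_min must not exceed eta_max")


def cosine_lr(t: int, total: int, eta_min: float, eta_max: float) -> float:
    """eta_t = eta_min + (eta_max - eta_min)(1 + cos(pi t / T)) / 2."""
    if t > total:
        logger.warning("step %d beyond schedule horizon %d; clamping", t, total)
        return eta_min
    return eta_min + 0.5 * (eta_max - eta_min) * (1 + math.cos(math.pi * t / total))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    accuracy: float
    precision: float               # macro (headline)
    recall: float
    f1: float
    map50: float
    topk: float
    k: int
    micro_precision: float
    micro_recall: float
    micro_f1: float
    confusion: dict                # per class: {tp, fp, fn, tn}

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "confusion"}
        return d


def _average_precision(scores: np.ndarray, hits: np.ndarray) -> float:
    """Area under the interpolated one-vs-rest precision-recall curve."""
    order = np.argsort(-scores, kind="stable")
    hits = hits[order]
    tp = np.cumsum(hits)
    fp = np.cumsum(~hits)
    n_pos = hits.sum()
    recall = tp / n_pos
    precision = tp / (tp + fp)
    # precision envelope (monotone non-increasing interpolation)
    for i in range(precision.size - 2, -1, -1):
        precision[i] = max(precision[i], precision[i + 1])
    ap = precision[0] * recall[0]
    for i in range(1, recall.size):
        ap += precision[i] * (recall[i] - recall[i - 1])
    return float(ap)


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    k: int = 5) -> MetricsReport:
    """Accuracy, macro/micro precision-recall-F1, PR-AUC mAP and top-k.

    ``scores``: (N, C) class scores per sample; ``labels``: (N,) integers.
    mAP here is the classification form: the mean over classes of the area
    under the one-vs-rest precision-recall curve.  Undefined per-class
    precision (no predictions for the class) counts as 0 with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.ndim != 2 or scores.shape[0] == 0:
        raise ValueError("scores must be a non-empty (N, C) array")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    n, c = scores.shape
    pred = scores.argmax(axis=1)
    accuracy = float((pred == labels).mean())

    confusion = {}
    precs, recs, f1s = [], [], []
    tp_sum = fp_sum = fn_sum = 0
    for cls in range(c):
        tp = int(((pred == cls) & (labels == cls)).sum())
        fp = int(((pred == cls) & (labels != cls)).sum())
        fn = int(((pred != cls) & (labels == cls)).sum())
        tn = n - tp - fp - fn
        confusion[cls] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
        if tp + fp == 0:
            logger.warning("class %d never predicted: precision set to 0", cls)
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        rec = tp / (tp + fn) if (tp + fn) else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
        tp_sum += tp
        fp_sum += fp
        fn_sum += fn

    micro_p = tp_sum / (tp_sum + fp_sum) if (tp_sum + fp_sum) else 0.0
    micro_r = tp_sum / (tp_sum + fn_sum) if (tp_sum + fn_sum) else 0.0
    micro_f1 = 2 * micro_p * micro_r / (micro_p + micro_r) \
        if (micro_p + micro_r) else 0.0

    aps = []
    for cls in range(c):
        hits = labels == cls
        if hits.any():
            aps.append(_average_precision(scores[:, cls], hits))
    map50 = float(np.mean(aps)) if aps else 0.0

    kk = min(k, c)
    topk_sets = np.argsort(-scores, axis=1)[:, :kk]
    topk = float(np.mean([labels[i] in topk_sets[i] for i in range(n)]))

    return MetricsReport(accuracy, float(np.mean(precs)), float(np.mean(recs)),
                         float(np.mean(f1s)), map50, topk, kk,
                         float(micro_p), float(micro_r), float(micro_f1),
                         confusion)


# ---------------------------------------------------------------------------
# SNR harness
# ---------------------------------------------------------------------------

@dataclass
class SNRSpec:
    target_snr_db: float = 20.0
    noise_kind: str = "gaussian"   # gaussian | wind | rustle | insect

    def __post_init__(self):
        if self.noise_kind not in ("gaussian", "wind", "rustle", "insect"):
            raise ValueError(f"unknown noise kind {self.noise_kind!r}")


def make_noise(kind: str, n: int, sample_rate: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS noise profile of the requested ecological flavour."""
    white = rng.standard_normal(n)
    nyq = sample_rate / 2.0
    if kind == "gaussian":
        noise = white
    elif kind == "wind":
        sos = butter(4, min(300.0, 0.9 * nyq) / nyq, btype="low", output="sos")
        noise = sosfiltfilt(sos, white)
    elif kind == "rustle":
        lo = min(2000.0, 0.5 * nyq)
        hi = min(6000.0, 0.95 * nyq)
        sos = butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
        noise = sosfiltfilt(sos, white)
    elif kind == "insect":
        t = np.arange(n) / sample_rate
        f0 = rng.uniform(300.0, 700.0)
        noise = sum(np.sin(2 * np.pi * f0 * h * t + rng.uniform(0, 2 * np.pi))
                    / h for h in (1, 2, 3))
        noise = noise + 0.05 * white
    else:
        raise ValueError(f"unknown noise kind {kind!r}")
    rms = np.sqrt(np.mean(noise ** 2))
    return noise / max(rms, 1e-12)


def mix_at_snr(clean: np.ndarray, noise: np.ndarray,
               target_snr_db: float) -> tuple[np.ndarray, float]:
    """Scale ``noise`` so that 10 log10(P_signal / P_noise) hits the target.

    ``target_snr_db = inf`` returns the clean signal unchanged.
    """
    if clean.shape != noise.shape:
        raise ValueError("clean and noise must have equal length")
    p_clean = float(np.mean(clean ** 2))
    if p_clean <= 0:
        raise ValueError("clean signal has zero power")
    if np.isinf(target_snr_db):
        return clean.copy(), float("inf")
    p_noise = float(np.mean(noise ** 2))
    if p_noise <= 0:
        raise ValueError("noise signal has zero power")
    scale = np.sqrt(p_clean / (p_noise * 10.0 ** (target_snr_db / 10.0)))
    mixed = clean + scale * noise
    achieved = 10.0 * np.log10(p_clean / (p_noise * scale ** 2))
    return mixed, float(achieved)


# ---------------------------------------------------------------------------
# data handling
# ---------------------------------------------------------------------------

def split_dataset(pairs: list, split: tuple, seed: int) -> tuple[list, list, list]:
    """Stratified train/val/test split of aligned pairs."""
    rng = np.random.default_rng(seed)
    labels = np.array([p.label for p in pairs])
    train_idx, val_idx, test_idx = [], [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n = idx.size
        n_train = int(round(split[0] * n))
        n_val = int(round(split[1] * n))
        train_idx += list(idx[:n_train])
        val_idx += list(idx[n_train:n_train + n_val])
        test_idx += list(idx[n_train + n_val:])
    return ([pairs[i] for i in train_idx], [pairs[i] for i in val_idx],
            [pairs[i] for i in test_idx])


@dataclass
class TrainResult:
    model: MultimodalClassifier
    explain: ExplainModule | None
    history: pd.DataFrame
    best_val_accuracy: float
    best_epoch: int


def _xai_step(model, explain_mod, out, images, mels, labels, masks,
              batch_slice, xai_cfg: XaiConfig, train_cfg: TrainConfig):
    """Explanation loss on a subsample; returns (loss tensor, scalar value)."""
    total = None
    count = 0
    for i in batch_slice:
        cls = int(labels[i])
        hv = visual_saliency(model, images, mels, cls, batch_index=i)
        ha, _ = acoustic_saliency(
            model, images, mels, cls, batch_index=i,
            config=XaiConfig(ig_steps=max(8, train_cfg.ig_steps_train),
                             ig_baseline=xai_cfg.ig_baseline))
        hv_t = Tensor(hv.grid.astype(DTYPE))
        ha_t = Tensor(ha.grid.astype(DTYPE))
        gate = explain_mod.gate(hv_t.reshape(1, 64, 64),
                                ha_t.reshape(1, 64, 64)).reshape(64, 64)
        hc = gate * hv_t + (gate * (-1.0) + 1.0) * ha_t
        mc = attention_marginal(out.fusion, batch_index=i)
        mask = np.ones((8, 8, 1)) if masks[i] is None else \
            mask_to_feature_grid(masks[i], (8, 8))[..., None]
        part, _ = loss_xai(hc, mc, out.fv.grid[i], mask, xai_cfg)
        # interpreter heads regress onto the gradient-based maps
        from .encoders import FeatureMap
        fv_det = FeatureMap(out.fv.grid[i:i + 1].detach(), "visual")
        fa_det = FeatureMap(out.fa.grid[i:i + 1].detach(), "acoustic")
        iv = explain_mod.interp_visual(fv_det)[0]
        ia = explain_mod.interp_acoustic(fa_det)[0]
        reg = ((iv - hv_t) ** 2.0).mean() + ((ia - ha_t) ** 2.0).mean()
        part = part + reg * 0.1
        total = part if total is None else total + part
        count += 1
    if total is None:
        return None, 0.0
    total = total * (1.0 / count)
    return total, float(total.data)


def _noise_augment(pair, train_cfg: TrainConfig, rng: np.random.Generator):
    """Corrupt one pair's audio at a random SNR from the configured range."""
    if pair.waveform is None:
        return pair
    import copy
    q = copy.copy(pair)
    snr = rng.uniform(*train_cfg.noise_snr_range)
    noise = make_noise(train_cfg.noise_kind, q.waveform.size,
                       train_cfg.sample_rate, rng)
    mixed, _ = mix_at_snr(q.waveform, noise, snr)
    q.melspec = dsp.melspectrogram(mixed, train_cfg.sample_rate,
                                   pair.melspec.shape[0])
    return q


def train(pairs: list, train_cfg: TrainConfig,
          model_cfg: ModelConfig | None = None,
          xai_cfg: XaiConfig | None = None,
          val_pairs: list | None = None,
          similar_to: dict | None = None,
          out_dir: str | Path | None = None) -> TrainResult:
    """Optimise the joint objective; returns the best-validation model.

    Weakly aligned pairs are excluded from supervised multimodal training.
    If ``val_pairs`` is None the configured split is applied to ``pairs``.
    """
    model_cfg = model_cfg or ModelConfig()
    xai_cfg = xai_cfg or XaiConfig()
    rng = np.random.default_rng(train_cfg.seed)
    aligned = [p for p in pairs if p.aligned_flag]
    if val_pairs is None:
        train_pairs, val_pairs, _ = split_dataset(aligned, train_cfg.split,
                                                  train_cfg.seed)
    else:
        train_pairs = aligned
    labels_all = [p.label for p in train_pairs]
    if len(set(labels_all)) < 2:
        raise ValueError("training requires at least two classes")

    model = MultimodalClassifier(model_cfg, rng)
    use_xai = (train_cfg.use_xai and model_cfg.modality == "multimodal"
               and model_cfg.use_fusion)
    explain_mod = ExplainModule(model_cfg.encoder.shared_dim, rng) \
        if use_xai else None
    params = model.parameters() + (explain_mod.parameters() if explain_mod
                                   else [])
    opt = nn.AdamW(params, lr=train_cfg.eta_max, betas=train_cfg.betas,
                   weight_decay=train_cfg.weight_decay)

    n_train = len(train_pairs)
    steps_per_epoch = max(1, math.ceil(n_train / train_cfg.batch_size))
    total_steps = steps_per_epoch * train_cfg.epochs
    val_imgs, val_mels, val_labels = make_input_tensors(val_pairs,
                                                        model_cfg.encoder)
    history = []
    best_acc, best_epoch, best_state = -1.0, -1, None
    best_explain_state = None
    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n_train)
        ep = {"lcls": 0.0, "lcs": 0.0, "lmargin": 0.0, "lxai": 0.0,
              "ltotal": 0.0}
        for b0 in range(0, n_train, train_cfg.batch_size):
            batch = [train_pairs[i] for i in order[b0:b0 + train_cfg.batch_size]]
            if train_cfg.noise_snr_range is not None:
                batch = [_noise_augment(p, train_cfg, rng) for p in batch]
            images, mels, labels = make_input_tensors(batch, model_cfg.encoder)
            masks = [p.mask for p in batch]
            opt.lr = cosine_lr(step, total_steps, train_cfg.eta_min,
                               train_cfg.eta_max)
            opt.zero_grad()
            out = model(images, mels)
            l_cls = F.cross_entropy(out.logits, labels)
            zero = Tensor(np.zeros((), dtype=DTYPE))
            l_cs, l_margin = zero, zero
            label_counts = np.bincount(labels)
            has_positive = np.any(label_counts >= 2)
            if train_cfg.use_contrast and len(set(labels.tolist())) >= 2 \
                    and has_positive \
                    and out.v_pool is not None and out.a_pool is not None:
                from .contrast import project_joint
                _, _, zm = project_joint(out.v_pool, out.a_pool,
                                         model.contrast_head)
                pb = build_pairs(zm, labels, similar_to=similar_to)
                batch_emb = EmbeddingBatch(zm, pb.labels, pb.similarity,
                                           pb.positives, pb.negatives)
                l_cs = loss_infonce(batch_emb, model_cfg.contrast)
                l_margin = loss_margin(batch_emb, model_cfg.contrast)
            loss = loss_total(l_cls, l_cs, l_margin, model_cfg.contrast)
            l_xai_val = 0.0
            if use_xai and step % train_cfg.xai_every == 0 and \
                    out.fusion is not None:
                subsample = list(range(min(train_cfg.xai_samples, len(batch))))
                xai_loss, l_xai_val = _xai_step(
                    model, explain_mod, out, images, mels, labels, masks,
                    subsample, xai_cfg, train_cfg)
                if xai_loss is not None:
                    loss = loss + xai_loss
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch} step {step}")
            loss.backward()
            opt.step()
            step += 1
            ep["lcls"] += l_cls.item()
            ep["lcs"] += float(l_cs.data)
            ep["lmargin"] += float(l_margin.data)
            ep["lxai"] += l_xai_val
            ep["ltotal"] += float(loss.data)
        val_report = _evaluate_tensors(model, val_imgs, val_mels, val_labels)
        row = {"epoch": epoch, "lr": opt.lr,
               **{k: v / steps_per_epoch for k, v in ep.items()},
               "val_accuracy": val_report.accuracy,
               "val_f1": val_report.f1}
        history.append(row)
        if val_report.accuracy > best_acc:
            best_acc = val_report.accuracy
            best_epoch = epoch
            best_state = model.state_dict()
            best_explain_state = explain_mod.state_dict() if explain_mod else None
        elif epoch - best_epoch >= train_cfg.patience:
            logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
        if explain_mod is not None and best_explain_state is not None:
            explain_mod.load_state_dict(best_explain_state)
    hist = pd.DataFrame(history)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        hist.to_csv(out / "training_log.csv", index=False)
        save_checkpoint(out / "checkpoint.npz", model)
    return TrainResult(model, explain_mod, hist, best_acc, best_epoch)


def _evaluate_tensors(model, images, mels, labels) -> MetricsReport:
    model.eval()
    with nn.no_grad():
        out = model(images, mels)
    model.train()
    return compute_metrics(out.logits.data, labels, k=5)


def evaluate(model: MultimodalClassifier, pairs: list,
             snr_db: float | None = None, noise_kind: str = "gaussian",
             sample_rate: float = 22050, seed: int = 0) -> MetricsReport:
    """Metrics on a pair list, optionally after acoustic corruption at a SNR."""
    if snr_db is not None:
        rng = np.random.default_rng(seed)
        corrupted = []
        import copy
        for p in pairs:
            q = copy.deepcopy(p)
            noise = make_noise(noise_kind, q.waveform.size, sample_rate, rng)
            mixed, _ = mix_at_snr(q.waveform, noise, snr_db)
            q.waveform = mixed
            q.melspec = dsp.melspectrogram(mixed, sample_rate,
                                           p.melspec.shape[0])
            corrupted.append(q)
        pairs = corrupted
    images, mels, labels = make_input_tensors(pairs, model.config.encoder)
    if model.config.modality == "acoustic":
        images = None
    if model.config.modality == "visual":
        mels = None
    model.eval()
    with nn.no_grad():
        out = model(images, mels)
    return compute_metrics(out.logits.data, labels, k=5)


def kfold(pairs: list, k: int, runner, seed: int = 0) -> tuple[list, dict]:
    """Stratified k-fold protocol: each sample validated exactly once.

    ``runner(train_pairs, val_pairs, fold_index)`` must return a
    MetricsReport.  Falls back to unstratified folds when a class has fewer
    than k members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pairs) < k:
        raise ValueError("need at least k samples")
    labels = np.array([p.label for p in pairs])
    counts = np.bincount(labels)
    from sklearn.model_selection import KFold, StratifiedKFold
    if counts[counts > 0].min() < k:
        logger.warning("a class has fewer than k members; folds unstratified")
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(labels)
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        split_iter = splitter.split(labels, labels)
    reports = []
    for fold, (tr, va) in enumerate(split_iter):
        reports.append(runner([pairs[i] for i in tr], [pairs[i] for i in va],
                              fold))
    acc = [r.accuracy for r in reports]
    f1 = [r.f1 for r in reports]
    summary = {"accuracy_mean": float(np.mean(acc)),
               "accuracy_sd": float(np.std(acc, ddof=1)) if k > 1 else 0.0,
               "f1_mean": float(np.mean(f1)),
               "f1_sd": float(np.std(f1, ddof=1)) if k > 1 else 0.0}
    return reports, summary
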