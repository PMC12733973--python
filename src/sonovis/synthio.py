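"""Synthetic paired image/audio datasets for natural-enemy recognition.

Real field recordings of beneficial insects (lady beetles, lacewings,
parasitoid wasps, ...) pair a photograph of the animal with a short audio
clip dominated by its wingbeat.  This module generates a structurally
faithful stand-in: each species class has a distinct visual morphology
(elliptical body with a pronotum band and a spot pattern) and a distinct
acoustic signature (wingbeat fundamental plus harmonics, amplitude
modulated over a Gaussian noise floor).  Designated "similar" class pairs
differ in a single visual attribute and by at most 15% in wingbeat
frequency, so they exercise hard-negative mining downstream.  A small
fraction of pairs is flagged weakly aligned (a second species' call mixed
in at equal power) and excluded from supervised multimodal training.

All randomness flows from one seed; per-sample substreams are derived by
counter so regeneration is reproducible sample-by-sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import dsp

logger = logging.getLogger(__name__)

__all__ = ["SpeciesSpec", "SyntheticDatasetConfig", "AlignedPair",
           "make_species_bank", "render_image", "synth_clip",
           "make_background_pool", "build_dataset", "load_dataset"]

WEAK_FRACTION = 0.05  # fraction of pairs flagged weakly aligned


@dataclass
class SpeciesSpec:
    """Morphological and acoustic signature of one synthetic species."""

    class_id: int
    spot_count: int
    spot_layout: list          # fractional (x, y) coordinates in [0, 1]^2
    body_hue: tuple            # RGB in [0, 1]
    pronotum_hue: tuple
    wingbeat_hz: float         # fundamental wingbeat frequency
    harmonic_weights: list     # non-negative weights for harmonics 1, 2, ...
    similar_to: int | None = None

    def validate(self, sample_rate: float | None = None):
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if self.wingbeat_hz <= 0:
            raise ValueError("wingbeat_hz must be positive")
        if sample_rate is not None and self.wingbeat_hz >= sample_rate / 2:
            raise ValueError("wingbeat_hz must be below Nyquist")
        if any(w < 0 for w in self.harmonic_weights):
            raise ValueError("harmonic_weights must be non-negative")
        for x, y in self.spot_layout:
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise ValueError(f"spot coordinate ({x}, {y}) outside [0, 1]")


@dataclass
class SyntheticDatasetConfig:
    n_classes: int = 3
    samples_per_class: int = 20
    image_size: int = 128
    sample_rate: int = 22050
    clip_seconds: float = 1.0
    mel_bins: int = 64
    timestamp_jitter_sd: float = 0.02   # seconds between the two streams
    background_pool_size: int = 8
    noise_floor: float = 0.01           # RMS of the Gaussian floor in clips
    seed: int = 0

    def validate(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        for name in ("samples_per_class", "image_size", "sample_rate",
                     "mel_bins", "background_pool_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.clip_seconds * self.sample_rate < 1:
            raise ValueError("clip too short for the sample rate")
        if self.timestamp_jitter_sd < 0:
            raise ValueError("timestamp_jitter_sd must be >= 0")


@dataclass
class AlignedPair:
    """One synchronised training sample: image grid + mel spectrogram."""

    image: np.ndarray          # (H, W, 3) in [0, 1]
    melspec: np.ndarray        # (F, T) non-negative
    label: int
    t_visual: float
    t_acoustic: float
    aligned_flag: bool = True
    mask: np.ndarray | None = None      # (H, W) foreground mask
    waveform: np.ndarray | None = None  # raw audio, kept for SNR experiments

    def validate(self):
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        if self.melspec.min() < 0:
            raise ValueError("melspec values must be non-negative")


# ---------------------------------------------------------------------------
# species bank
# ---------------------------------------------------------------------------

def _hue_to_rgb(h: float) -> tuple:
    """Saturated colour wheel; spreads class body colours apart."""
    h6 = (h % 1.0) * 6.0
    x = 1.0 - abs(h6 % 2.0 - 1.0)
    rgb = [(1, x, 0), (x, 1, 0), (0, 1, x), (0, x, 1), (x, 0, 1), (1, 0, x)][int(h6) % 6]
    return tuple(0.15 + 0.75 * np.asarray(rgb))


def make_species_bank(n_classes: int, seed: int) -> list[SpeciesSpec]:
    """Deterministic bank of species signatures with designated confusable pairs.

    Every even-indexed class is paired with the next class: the partner shares
    the body colour and spot pattern (it differs only in the pronotum colour)
    and its wingbeat fundamental lies within 15% of its twin's.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = np.random.default_rng(seed)
    bank: list[SpeciesSpec] = []
    for cid in range(n_classes):
        if cid % 2 == 0 or not bank:
            spot_count = int(rng.integers(2, 7))
            layout = [(float(x), float(y))
                      for x, y in rng.uniform(0.25, 0.75, size=(spot_count, 2))]
            body = _hue_to_rgb(cid / n_classes + rng.uniform(-0.02, 0.02))
            pron = _hue_to_rgb(cid / n_classes + 0.45 + rng.uniform(-0.02, 0.02))
            wing = float(rng.uniform(150.0, 850.0))
            weights = list(np.round(rng.dirichlet([2.0, 1.0, 1.0]), 4))
            spec = SpeciesSpec(cid, spot_count, layout, body, pron, wing, weights,
                               similar_to=cid + 1 if cid + 1 < n_classes else None)
        else:
            twin = bank[cid - 1]
            pron = _hue_to_rgb(cid / n_classes + 0.2 + rng.uniform(-0.02, 0.02))
            wing = twin.wingbeat_hz * float(1.0 + rng.uniform(-0.12, 0.12))
            spec = SpeciesSpec(cid, twin.spot_count, list(twin.spot_layout),
                               twin.body_hue, pron, wing,
                               list(twin.harmonic_weights), similar_to=cid - 1)
        spec.validate()
        bank.append(spec)
    return bank


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def make_background_pool(pool_size: int, image_size: int, seed: int) -> list[np.ndarray]:
    """Smooth, vegetation-tinted random backgrounds."""
    pool = []
    for j in range(pool_size):
        rng = np.random.default_rng([seed, 1_000_000 + j])
        base = gaussian_filter(rng.uniform(size=(image_size, image_size, 3)),
                               sigma=(6, 6, 0))
        tint = np.array([0.35, 0.55, 0.30]) + rng.uniform(-0.1, 0.1, 3)
        bg = np.clip(base * 0.5 + tint * 0.5, 0, 1)
        pool.append(bg)
    return pool


def render_image(spec: SpeciesSpec, background: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Composite the species body onto ``background``; returns (image, mask).

    The body is an ellipse with a pronotum band at the anterior end and
    ``spot_count`` dark spots at the fractional ``spot_layout`` positions
    (expressed in the body's own frame).  The binary mask marks foreground
    pixels and is reused by background replacement and class gating.
    """
    spec.validate()
    h, w = background.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    u = (xx + 0.5) / w
    v = (yy + 0.5) / h

    cx = 0.5 + float(rng.uniform(-0.06, 0.06))
    cy = 0.5 + float(rng.uniform(-0.06, 0.06))
    theta = float(rng.uniform(0, np.pi))
    a, b = 0.28, 0.18  # semi-axes in fractional units
    ct, st = np.cos(theta), np.sin(theta)
    xr = (u - cx) * ct + (v - cy) * st
    yr = -(u - cx) * st + (v - cy) * ct
    body = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    mask = body.astype(np.float64)

    img = background.astype(np.float64).copy()
    shade = 1.0 - 0.35 * ((xr / a) ** 2 + (yr / b) ** 2)
    for c in range(3):
        img[..., c] = np.where(body, spec.body_hue[c] * np.clip(shade, 0, 1),
                               img[..., c])

    # pronotum: band near the anterior end of the major axis
    pron = ((xr + 0.6 * a) / (0.35 * a)) ** 2 + (yr / (0.8 * b)) ** 2 <= 1.0
    pron &= body
    for c in range(3):
        img[..., c] = np.where(pron, spec.pronotum_hue[c], img[..., c])

    # spots in the body frame
    r_spot = 0.035
    for sx, sy in spec.spot_layout:
        px = (sx - 0.5) * 2 * a * 0.8
        py = (sy - 0.5) * 2 * b * 0.8
        spot = ((xr - px) ** 2 + (yr - py) ** 2) <= r_spot ** 2
        spot &= body
        img[spot] = 0.05

    return np.clip(img, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# audio synthesis
# ---------------------------------------------------------------------------

def synth_clip(spec: SpeciesSpec, clip_seconds: float, sample_rate: float,
               rng: np.random.Generator, noise_floor: float = 0.01) -> np.ndarray:
    """Amplitude-modulated harmonic stack at the wingbeat fundamental.

    Harmonics above Nyquist are dropped with a logged warning.  Peak amplitude
    is normalised to at most 1.
    """
    spec.validate(sample_rate)
    n = int(round(clip_seconds * sample_rate))
    if n < 1:
        raise ValueError("clip_seconds * sample_rate must be >= 1")
    t = np.arange(n) / sample_rate
    signal = np.zeros(n)
    for k, wgt in enumerate(spec.harmonic_weights, start=1):
        f = spec.wingbeat_hz * k
        if f >= sample_rate / 2:
            logger.warning("harmonic %d at %.1f Hz above Nyquist; dropped", k, f)
            continue
        phase = rng.uniform(0, 2 * np.pi)
        signal += wgt * np.sin(2 * np.pi * f * t + phase)
    # slow amplitude modulation: wing muscle bursts
    f_am = rng.uniform(3.0, 8.0)
    env = 0.6 + 0.4 * np.sin(2 * np.pi * f_am * t + rng.uniform(0, 2 * np.pi))
    signal *= env
    signal += noise_floor * rng.standard_normal(n)
    peak = np.abs(signal).max()
    if peak > 1.0:
        signal /= peak
    return signal


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def build_dataset(config: SyntheticDatasetConfig,
                  out_dir: str | Path | None = None
                  ) -> tuple[list[AlignedPair], dict]:
    """Generate ``n_classes * samples_per_class`` aligned pairs.

    Visual timestamps advance on a regular grid; the acoustic timestamp of
    each pair is offset by Normal(0, jitter_sd).  About 5% of pairs are
    flagged weakly aligned: a clip from another species is mixed in at equal
    power, mirroring overlapping-call field recordings.  When ``out_dir`` is
    given the dataset is also materialised as PNG + WAV + JSON labels +
    environment CSV + a YAML manifest.
    """
    config.validate()
    bank = make_species_bank(config.n_classes, config.seed)
    backgrounds = make_background_pool(config.background_pool_size,
                                       config.image_size, config.seed)
    master = np.random.default_rng([config.seed, 7])
    n_total = config.n_classes * config.samples_per_class
    weak = master.uniform(size=n_total) < WEAK_FRACTION

    pairs: list[AlignedPair] = []
    labels_doc: dict[str, dict] = {}
    env_rows = []
    idx = 0
    for cid in range(config.n_classes):
        for _ in range(config.samples_per_class):
            rng = np.random.default_rng([config.seed, idx])
            bg = backgrounds[int(rng.integers(len(backgrounds)))]
            image, mask = render_image(bank[cid], bg, rng)
            wave = synth_clip(bank[cid], config.clip_seconds, config.sample_rate,
                              rng, config.noise_floor)
            flag = True
            if weak[idx]:
                other = int((cid + 1 + rng.integers(config.n_classes - 1))
                            % config.n_classes)
                intruder = synth_clip(bank[other], config.clip_seconds,
                                      config.sample_rate, rng, config.noise_floor)
                p_w = np.mean(wave ** 2)
                p_i = np.mean(intruder ** 2)
                wave = wave + intruder * np.sqrt(p_w / max(p_i, 1e-12))
                peak = np.abs(wave).max()
                if peak > 1.0:
                    wave /= peak
                flag = False
            mel = dsp.melspectrogram(wave, config.sample_rate, config.mel_bins)
            t_vis = idx * (config.clip_seconds + 1.0)
            t_ac = t_vis + float(rng.normal(0.0, config.timestamp_jitter_sd)) \
                if config.timestamp_jitter_sd > 0 else t_vis
            pair = AlignedPair(image=image, melspec=mel, label=cid,
                               t_visual=t_vis, t_acoustic=t_ac,
                               aligned_flag=flag, mask=mask, waveform=wave)
            pair.validate()
            pairs.append(pair)
            stem = f"{idx:05d}"
            labels_doc[stem] = {"class_id": cid, "aligned_flag": bool(flag),
                                "t_visual": float(t_vis), "t_acoustic": float(t_ac)}
            env_rows.append({"timestamp": float(t_vis),
                             "temperature": 18.0 + 8.0 * rng.beta(2, 2),
                             "humidity": 40.0 + 35.0 * rng.beta(2, 2),
                             "light": float(rng.uniform(100.0, 1200.0))})
            idx += 1

    manifest = {
        "n_pairs": n_total,
        "n_classes": config.n_classes,
        "samples_per_class": config.samples_per_class,
        "image_size": config.image_size,
        "sample_rate": config.sample_rate,
        "clip_seconds": config.clip_seconds,
        "mel_bins": config.mel_bins,
        "seed": config.seed,
        "label_histogram": {c: config.samples_per_class
                            for c in range(config.n_classes)},
        "weakly_aligned": int(np.sum(weak)),
    }

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "audio").mkdir(parents=True, exist_ok=True)
        for i, pair in enumerate(pairs):
            stem = f"{i:05d}"
            Image.fromarray((pair.image * 255).astype(np.uint8)).save(
                out / "images" / f"{stem}.png")
            dsp.write_wav(out / "audio" / f"{stem}.wav", pair.waveform,
                          config.sample_rate)
        (out / "labels.json").write_text(json.dumps(labels_doc, indent=1))
        pd.DataFrame(env_rows).to_csv(out / "environment.csv", index=False)
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))

    return pairs, manifest


def load_dataset(data_dir: str | Path) -> tuple[list[AlignedPair], dict]:
    """Read a materialised dataset directory back into aligned pairs.

    Expects the layout written by :func:`build_dataset` (images/, audio/,
    labels.json, manifest.yaml).  Mel spectrograms are recomputed from the
    WAV files with the manifest's parameters.  Foreground masks are not part
    of the on-disk format and come back as ``None``.
    """
    root = Path(data_dir)
    manifest = yaml.safe_load((root / "manifest.yaml").read_text())
    labels_doc = json.loads((root / "labels.json").read_text())
    pairs: list[AlignedPair] = []
    for stem in sorted(labels_doc):
        rec = labels_doc[stem]
        image = np.asarray(Image.open(root / "images" / f"{stem}.png"),
                           dtype=np.float64) / 255.0
        wave, sr = dsp.read_wav(root / "audio" / f"{stem}.wav")
        mel = dsp.melspectrogram(wave, sr, manifest["mel_bins"])
        pairs.append(AlignedPair(
            image=image, melspec=mel, label=int(rec["class_id"]),
            t_visual=float(rec["t_visual"]),
            t_acoustic=float(rec["t_acoustic"]),
            aligned_flag=bool(rec["aligned_flag"]),
            mask=None, waveform=wave))
    return pairs, manifest
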