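"""Paired visual/acoustic augmentation operators.

Six operators: random crop with bilinear resampling, photometric jitter
(contrast/brightness on the 8-bit convention), background replacement under
a binary foreground mask, temporal shift of the waveform with zero padding,
additive Gaussian noise, and separable smoothing of the mel spectrogram.
``paired_augment`` applies them with a single shared random state and keeps
the two streams temporally coherent: an acoustic time shift updates the
pair's acoustic timestamp so downstream consistency checks remain valid.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve1d, map_coordinates

from .synthio import AlignedPair

logger = logging.getLogger(__name__)

__all__ = ["AugmentSpec", "random_crop", "jitter_photometric",
           "replace_background", "shift_time", "add_noise",
           "smooth_spectrogram", "paired_augment", "sample_augment_spec"]


@dataclass
class AugmentSpec:
    """One concrete draw of augmentation parameters."""

    crop_ratio: float = 1.0        # alpha in (0, 1]
    dx: float = 0.0                # crop offsets, pixels
    dy: float = 0.0
    brightness: float = 0.0        # b, intensity units on [0, 255]
    contrast: float = 1.0          # c, multiplier
    noise_scale: float = 0.0       # lambda >= 0
    noise_sd: float = 1.0          # sigma of n(t)
    time_shift: float = 0.0        # delta-t, seconds
    kernel_f: np.ndarray = field(default_factory=lambda: np.array([1.0]))
    kernel_t: np.ndarray = field(default_factory=lambda: np.array([1.0]))

    def __post_init__(self):
        if not (0.0 < self.crop_ratio <= 1.0):
            raise ValueError("crop_ratio must lie in (0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        self.kernel_f = np.asarray(self.kernel_f, dtype=float)
        self.kernel_t = np.asarray(self.kernel_t, dtype=float)
        for name in ("kernel_f", "kernel_t"):
            k = getattr(self, name)
            if np.any(k < 0) or k.sum() <= 0:
                raise ValueError(f"{name} must be non-negative with positive sum")
            setattr(self, name, k / k.sum())


# default sampling ranges for random draws
DEFAULT_RANGES = {
    "crop_ratio": (0.7, 1.0),
    "brightness": (-20.0, 20.0),
    "contrast": (0.8, 1.2),
    "noise_scale": (0.0, 0.1),
    "time_shift": (-0.1, 0.1),
}


def sample_augment_spec(rng: np.random.Generator,
                        ranges: dict | None = None) -> AugmentSpec:
    r = dict(DEFAULT_RANGES)
    if ranges:
        r.update(ranges)
    alpha = float(rng.uniform(*r["crop_ratio"]))
    return AugmentSpec(
        crop_ratio=alpha,
        dx=float(rng.uniform(-4, 4)),
        dy=float(rng.uniform(-4, 4)),
        brightness=float(rng.uniform(*r["brightness"])),
        contrast=float(rng.uniform(*r["contrast"])),
        noise_scale=float(rng.uniform(*r["noise_scale"])),
        time_shift=float(rng.uniform(*r["time_shift"])),
        kernel_f=np.array([0.25, 0.5, 0.25]),
        kernel_t=np.array([0.25, 0.5, 0.25]),
    )


def random_crop(image: np.ndarray, alpha: float, dx: float, dy: float) -> np.ndarray:
    """Sample I(alpha*x + dx, alpha*y + dy) bilinearly, output at input size.

    Windows reaching outside the image are clamped to the border (logged, not
    an error).
    """
    if alpha <= 0:
        raise ValueError("crop ratio must be positive")
    h, w = image.shape[:2]
    ys = alpha * np.arange(h) + dy
    xs = alpha * np.arange(w) + dx
    if ys[0] < 0 or xs[0] < 0 or ys[-1] > h - 1 or xs[-1] > w - 1:
        logger.info("crop window clamped to image bounds")
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    coords = np.stack([yy.ravel(), xx.ravel()])
    out = np.empty_like(image, dtype=float)
    if image.ndim == 2:
        return map_coordinates(image, coords, order=1, mode="nearest").reshape(h, w)
    for c in range(image.shape[2]):
        out[..., c] = map_coordinates(image[..., c], coords, order=1,
                                      mode="nearest").reshape(h, w)
    return out


def jitter_photometric(image: np.ndarray, contrast: float,
                       brightness: float) -> np.ndarray:
    """p' = clip(c*p + b, 0, 255); image given in the 8-bit convention."""
    return np.clip(contrast * image + brightness, 0.0, 255.0)


def replace_background(image: np.ndarray, mask: np.ndarray,
                       background: np.ndarray) -> np.ndarray:
    """I_bg = M*I + (1-M)*B with a binary foreground mask M."""
    if image.shape != background.shape:
        raise ValueError("image and background shapes differ")
    m = np.asarray(mask, dtype=float)
    if not np.all(np.isin(m, (0.0, 1.0))):
        raise ValueError("mask must be binary")
    if m.ndim == image.ndim - 1:
        m = m[..., None]
    return m * image + (1.0 - m) * background


def shift_time(waveform: np.ndarray, delta_t: float,
               sample_rate: float) -> np.ndarray:
    """s_shift(t) = s(t + delta_t); vacated samples zero-padded, length kept."""
    n = waveform.size
    if abs(delta_t) * sample_rate >= n:
        raise ValueError("time shift exceeds clip length")
    k = int(round(delta_t * sample_rate))
    out = np.zeros_like(waveform)
    if k >= 0:
        out[: n - k] = waveform[k:]
    else:
        out[-k:] = waveform[: n + k]
    return out


def add_noise(waveform: np.ndarray, noise_scale: float, noise_sd: float,
              rng: np.random.Generator) -> np.ndarray:
    """s + lambda * n with n ~ N(0, sigma^2)."""
    if noise_scale < 0:
        raise ValueError("noise scale must be >= 0")
    if noise_scale == 0:
        return waveform.copy()
    return waveform + noise_scale * rng.normal(0.0, noise_sd, size=waveform.shape)


def smooth_spectrogram(melspec: np.ndarray, kernel_f: np.ndarray,
                       kernel_t: np.ndarray) -> np.ndarray:
    """Separable smoothing along frequency then time, reflective padding."""
    kernel_f = np.asarray(kernel_f, dtype=float)
    kernel_t = np.asarray(kernel_t, dtype=float)
    if kernel_f.size > melspec.shape[0] or kernel_t.size > melspec.shape[1]:
        raise ValueError("kernel longer than spectrogram axis")
    for k in (kernel_f, kernel_t):
        if abs(k.sum() - 1.0) > 1e-8:
            raise ValueError("kernels must be normalised to sum 1")
    out = convolve1d(melspec, kernel_f, axis=0, mode="reflect")
    return convolve1d(out, kernel_t, axis=1, mode="reflect")


def paired_augment(pair: AlignedPair, spec: AugmentSpec,
                   rng: np.random.Generator, sample_rate: float,
                   mel_bins: int = 64, background: np.ndarray | None = None,
                   ) -> AlignedPair:
    """Apply coherent visual + acoustic augmentation from one shared rng.

    The acoustic time shift updates ``t_acoustic`` so that the pair's
    bookkeeping stays consistent with the signal content; the label is never
    touched.  The mel spectrogram is recomputed from the augmented waveform
    and then smoothed.
    """
    from . import dsp  # local import to avoid cycle at module load

    out = copy.deepcopy(pair)
    img255 = out.image * 255.0
    img255 = random_crop(img255, spec.crop_ratio, spec.dx, spec.dy)
    img255 = jitter_photometric(img255, spec.contrast, spec.brightness)
    out.image = img255 / 255.0
    if background is not None and out.mask is not None:
        # crop moves the body; recompute the mask through the same warp
        mask = random_crop(pair.mask.astype(float), spec.crop_ratio,
                           spec.dx, spec.dy)
        mask = (mask > 0.5).astype(float)
        out.image = replace_background(out.image, mask, background)
        out.mask = mask
    if out.waveform is not None:
        wave = out.waveform
        if spec.time_shift != 0.0:
            wave = shift_time(wave, spec.time_shift, sample_rate)
            out.t_acoustic = out.t_acoustic + spec.time_shift
        wave = add_noise(wave, spec.noise_scale, spec.noise_sd, rng)
        out.waveform = wave
        mel = dsp.melspectrogram(wave, sample_rate, mel_bins)
        out.melspec = smooth_spectrogram(mel, spec.kernel_f, spec.kernel_t)
    return out
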