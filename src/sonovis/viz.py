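"""Overlay rendering for saliency maps."""

from __future__ import annotations

from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image

from .nn.functional import resize_matrix

__all__ = ["save_overlay"]


def save_overlay(base: np.ndarray, heatmap: np.ndarray, path: str | Path,
                 alpha: float = 0.5, cmap: str = "magma"):
    """Alpha-blend a heatmap onto an image (or spectrogram) and save a PNG.

    ``base``: (H, W, 3) in [0, 1] or (F, T) grayscale; ``heatmap``: any 2-D
    non-negative map, resized to the base resolution.
    """
    base = np.asarray(base, dtype=float)
    if base.ndim == 2:
        lo, hi = base.min(), base.max()
        base = (base - lo) / (hi - lo + 1e-12)
        base = np.repeat(base[..., None], 3, axis=-1)
    h, w = base.shape[:2]
    ry = resize_matrix(h, heatmap.shape[0])
    rx = resize_matrix(w, heatmap.shape[1])
    hm = ry @ np.asarray(heatmap, dtype=float) @ rx.T
    hm = (hm - hm.min()) / (hm.max() - hm.min() + 1e-12)
    colors = matplotlib.colormaps[cmap](hm)[..., :3]
    blend = np.clip((1 - alpha) * base + alpha * colors, 0, 1)
    Image.fromarray((blend * 255).astype(np.uint8)).save(str(path))
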