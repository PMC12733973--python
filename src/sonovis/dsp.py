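"""Audio signal processing: STFT-based mel spectrograms and WAV round-trips.

The acoustic branch consumes mel spectrograms: the magnitude STFT warped onto
a mel-scaled frequency axis.  Window/hop defaults are 25 ms / 10 ms, the
common bioacoustics configuration for short insect wingbeat clips.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import stft

__all__ = ["hz_to_mel", "mel_to_hz", "mel_filterbank", "melspectrogram",
           "write_wav", "read_wav"]


def hz_to_mel(f):
    """HTK mel scale."""
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, sample_rate: float,
                   fmin: float = 30.0, fmax: float | None = None) -> np.ndarray:
    """Triangular mel filterbank, shape (n_mels, n_fft//2 + 1)."""
    if fmax is None:
        fmax = sample_rate / 2.0
    mel_pts = np.linspace(hz_to_mel(fmin), hz_to_mel(fmax), n_mels + 2)
    hz_pts = mel_to_hz(mel_pts)
    fft_freqs = np.linspace(0.0, sample_rate / 2.0, n_fft // 2 + 1)
    fb = np.zeros((n_mels, fft_freqs.size))
    for i in range(n_mels):
        left, center, right = hz_pts[i], hz_pts[i + 1], hz_pts[i + 2]
        up = (fft_freqs - left) / max(center - left, 1e-9)
        down = (right - fft_freqs) / max(right - center, 1e-9)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def melspectrogram(waveform: np.ndarray, sample_rate: float,
                   n_mels: int = 64, win_seconds: float = 0.025,
                   hop_seconds: float = 0.010, log: bool = True) -> np.ndarray:
    """Mel power spectrogram (n_mels, n_frames), non-negative.

    With ``log`` the map is log1p-compressed, which keeps it non-negative
    while taming the dynamic range of harmonic stacks.
    """
    nper = max(16, int(round(win_seconds * sample_rate)))
    hop = max(1, int(round(hop_seconds * sample_rate)))
    _, _, z = stft(waveform, fs=sample_rate, nperseg=nper,
                   noverlap=nper - hop, boundary=None, padded=False)
    power = np.abs(z) ** 2
    fb = mel_filterbank(n_mels, nper, sample_rate)
    mel = fb @ power
    if log:
        mel = np.log1p(mel * 1e4)
    return mel


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int):
    """16-bit PCM mono WAV."""
    clipped = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (clipped * 32767).astype(np.int16))


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    sr, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(np.float64) / 32767.0
    return data, int(sr)
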