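"""Method-2 feature pipeline: framed log-power spectrogram.

The decision window is split into 1.4 s frames advancing every 0.2 s; each
frame's first 128 samples are Fourier-transformed and the one-sided power
spectrum is mapped to [0, 1] against a -100 dB noise floor:

    value = clip((10 log10(P + eps) - floor) / (-floor), 0, 1),
    eps = 10^(floor/10)

so silence sits exactly at 0 and a 0 dB component at 1.  At 128 Hz a 6 s
window yields 23 frames x 65 bins = 1495 values, the input size of the
convolutional classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import EcgSignal


@dataclass(frozen=True)
class SpectrogramParams:
    frame_s: float = 1.4
    stride_s: float = 0.2
    nfft: int = 128
    noise_floor_db: float = -100.0

    def __post_init__(self):
        if not 0 < self.stride_s <= self.frame_s:
            raise ValueError("need frame_s >= stride_s > 0")
        if self.nfft < 2 or (self.nfft & (self.nfft - 1)):
            raise ValueError("nfft must be a power of two")
        if not self.noise_floor_db < 0:
            raise ValueError("noise_floor_db must be negative")

    def frame_len(self, fs: float) -> int:
        return int(np.floor(self.frame_s * fs + 0.5))  # round-half-up

    def stride(self, fs: float) -> int:
        return int(np.floor(self.stride_s * fs + 0.5))

    @property
    def n_bins(self) -> int:
        return self.nfft // 2 + 1


@dataclass
class SpectrogramImage:
    """Time x frequency matrix of normalized log power, values in [0, 1]."""

    values: np.ndarray  # (n_frames, n_bins)
    params: SpectrogramParams
    fs: float

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Row-major (frame-major) flattening, the classifier input layout."""
        return self.values.reshape(-1)


def compute_spectrogram(window: EcgSignal, params: SpectrogramParams | None = None) -> SpectrogramImage:
    """Compute the normalized log-power spectrogram of a decision window.

    Frames longer than ``nfft`` are truncated to their first ``nfft``
    samples; shorter frames are zero-padded.  No taper is applied.
    """
    if params is None:
        params = SpectrogramParams()
    x = window.samples
    fs = window.fs
    flen = params.frame_len(fs)
    stride = params.stride(fs)
    if x.size < flen:
        raise ValueError(f"window holds {x.size} samples; one frame needs {flen}")
    n_frames = (x.size - flen) // stride + 1
    eps = 10.0 ** (params.noise_floor_db / 10.0)
    out = np.empty((n_frames, params.n_bins))
    for i in range(n_frames):
        seg = x[i * stride : i * stride + flen][: params.nfft]
        spec = np.fft.rfft(seg, n=params.nfft)
        power = (np.abs(spec) / params.nfft) ** 2
        db = 10.0 * np.log10(power + eps)
        out[i] = np.clip((db - params.noise_floor_db) / (-params.noise_floor_db), 0.0, 1.0)
    return SpectrogramImage(values=out, params=params, fs=fs)
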