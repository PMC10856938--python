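"""Method-1 feature pipeline: FIBF statistics over a sliding decision window.

A 6 s decision window is scanned with 2 s frames advancing every 0.5 s
(12 frames per window).  Each frame is decomposed into 4 FIBFs, each FIBF
is normalized, and five statistics are computed per FIBF — energy,
kurtosis, skewness, variance and spectral entropy — giving the
12 x 4 x 5 = 240-dimensional feature vector the dense classifier consumes.

Statistic definitions (population moments, raw kurtosis):

    energy   = sum y[n]^2
    kurtosis = (1/N) sum ((y - mean)/sigma)^4
    skewness = (1/N) sum ((y - mean)/sigma)^3
    variance = (1/N) sum (y - mean)^2
    entropy  = -sum P(n) log2 P(n),  P = |FFT(y)|^2 / sum |FFT(y)|^2

Degenerate conventions: sigma = 0 gives skewness = kurtosis = 0; an
all-zero spectrum gives entropy = 0 (0*log 0 := 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EcgSignal
from .fdm import BandSpec, decompose_fibf, default_band_edges

STAT_NAMES = ("energy", "kurtosis", "skewness", "variance", "entropy")

FRAME_S = 2.0
UPDATE_S = 0.5
WINDOW_S = 6.0


def normalize(vec: np.ndarray, mode: str = "maxabs") -> np.ndarray:
    """Amplitude normalization.

    ``range`` maps to [0, 1] via (x - min)/(max - min); ``maxabs`` maps to
    [-1, 1] via x / max|x|.  Degenerate inputs (zero range / all-zero) are
    rejected — callers that must tolerate them use :func:`safe_normalize`.
    """
    x = np.asarray(vec, dtype=float)
    if x.size == 0:
        raise ValueError("cannot normalize an empty vector")
    if mode == "range":
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError("range normalization undefined for constant input")
        return (x - lo) / (hi - lo)
    if mode == "maxabs":
        m = np.abs(x).max()
        if m == 0:
            raise ValueError("maxabs normalization undefined for an all-zero vector")
        return x / m
    raise ValueError(f"unknown normalization mode {mode!r} (expected 'range' or 'maxabs')")


def safe_normalize(vec: np.ndarray, mode: str = "maxabs") -> np.ndarray:
    """Like :func:`normalize` but passes degenerate input through unchanged."""
    try:
        return normalize(vec, mode)
    except ValueError:
        return np.asarray(vec, dtype=float)


@dataclass(frozen=True)
class FeatureTuple:
    """The five per-FIBF statistics, in the fixed E, K, S, V, H order."""

    energy: float
    kurtosis: float
    skewness: float
    variance: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array([self.energy, self.kurtosis, self.skewness, self.variance, self.entropy])


def fibf_features(fibf: np.ndarray) -> FeatureTuple:
    """Compute the five statistics of one (normalized) FIBF."""
    y = np.asarray(fibf, dtype=float)
    if y.size < 2:
        raise ValueError("fibf_features needs at least 2 samples")
    energy = float(np.sum(y**2))
    mean = y.mean()
    var = float(np.mean((y - mean) ** 2))
    sigma = np.sqrt(var)
    if sigma > 0:
        z = (y - mean) / sigma
        kurt = float(np.mean(z**4))
        skew = float(np.mean(z**3))
    else:
        kurt = skew = 0.0
    s = np.abs(np.fft.fft(y)) ** 2
    tot = s.sum()
    if tot > 0:
        p = s / tot
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
    else:
        entropy = 0.0
    return FeatureTuple(energy, kurt, skew, var, entropy)


@dataclass
class FeatureVector:
    """Ordered Method-1 feature vector for one decision window.

    Layout is frame-major: index = ((frame * n_bands) + band) * 5 + stat,
    with frames ordered oldest-to-newest by their end time and statistics
    in :data:`STAT_NAMES` order.
    """

    values: np.ndarray
    n_frames: int
    n_bands: int
    window_s: float = WINDOW_S
    update_s: float = UPDATE_S
    stat_names: tuple = field(default=STAT_NAMES)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expect = self.n_frames * self.n_bands * len(self.stat_names)
        if self.values.size != expect:
            raise ValueError(f"layout says {expect} features, values has {self.values.size}")

    def index(self, frame: int, band: int, stat: int) -> int:
        if not (0 <= frame < self.n_frames and 0 <= band < self.n_bands and 0 <= stat < len(self.stat_names)):
            raise IndexError("feature coordinates out of range")
        return (frame * self.n_bands + band) * len(self.stat_names) + stat

    def coords(self, index: int) -> tuple:
        ns = len(self.stat_names)
        if not 0 <= index < self.values.size:
            raise IndexError("feature index out of range")
        frame, rest = divmod(index, self.n_bands * ns)
        band, stat = divmod(rest, ns)
        return frame, band, stat


def frame_features(frame: np.ndarray, band_spec: BandSpec, fs: float, norm_mode: str = "maxabs") -> np.ndarray:
    """Decompose one frame and return its K x 5 statistics, flattened band-major."""
    fset = decompose_fibf(frame, band_spec, fs)
    out = np.empty(fset.n_bands * len(STAT_NAMES))
    for b in range(fset.n_bands):
        y = safe_normalize(fset.fibfs[b], norm_mode)
        out[b * len(STAT_NAMES) : (b + 1) * len(STAT_NAMES)] = fibf_features(y).as_array()
    return out


def method1_window_features(
    window: EcgSignal,
    band_spec: BandSpec | None = None,
    norm_mode: str = "maxabs",
    frame_s: float = FRAME_S,
    update_s: float = UPDATE_S,
    window_s: float = WINDOW_S,
    history: np.ndarray | None = None,
) -> FeatureVector:
    """Method-1 feature vector for one decision window.

    One frame is evaluated per ``update_s`` within the window: frame k
    (k = 1..F, F = window_s/update_s) covers the ``frame_s * fs`` most
    recent samples ending at t = k * update_s.  Early frames that reach
    before the window start draw on ``history`` (the samples immediately
    preceding the window) when given, and are left-padded with zeros
    otherwise — the isolated-window convention.
    """
    fs = window.fs
    if band_spec is None:
        band_spec = default_band_edges(fs)
    n_frames_f = window_s / update_s
    n_frames = int(round(n_frames_f))
    if abs(n_frames_f - n_frames) > 1e-9:
        raise ValueError(f"window_s={window_s} is not an integer multiple of update_s={update_s}")
    frame_len = int(round(frame_s * fs))
    win_len = int(round(window_s * fs))
    if window.n_samples < win_len:
        raise ValueError(f"window holds {window.n_samples} samples; {win_len} required")
    x = window.samples[-win_len:]
    hist = np.asarray(history, dtype=float) if history is not None else np.empty(0)
    step = int(round(update_s * fs))

    values = np.empty(n_frames * band_spec.n_bands * len(STAT_NAMES))
    width = band_spec.n_bands * len(STAT_NAMES)
    for k in range(1, n_frames + 1):
        end = k * step
        start = end - frame_len
        if start >= 0:
            frame = x[start:end]
        else:
            need = -start
            ctx = hist[-need:] if hist.size >= need else np.concatenate([np.zeros(need - hist.size), hist])
            frame = np.concatenate([ctx, x[:end]])
        values[(k - 1) * width : k * width] = frame_features(frame, band_spec, fs, norm_mode)
    return FeatureVector(values=values, n_frames=n_frames, n_bands=band_spec.n_bands,
                         window_s=window_s, update_s=update_s)
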