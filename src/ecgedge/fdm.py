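"""Fourier Decomposition Method (FDM).

Splits a frame x[n] into its mean value c0 plus K Fourier Intrinsic Band
Functions (FIBFs): zero-mean, band-limited, mutually orthogonal components
obtained with an ideal zero-phase DFT filter bank.  For band i with bin
boundaries K_{i-1} < K_i the mask keeps bins K_{i-1}+1 .. K_i together with
their conjugate mirror N-K_i .. N-K_{i-1}-1, and the FIBF is the real part
of the inverse DFT of the masked spectrum.  When the bands tile all bins
1..N/2 the decomposition reconstructs the frame exactly:

    x[n] = c0 + sum_i y_i[n]

and the y_i are orthogonal with Parseval-consistent energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default 4-band partition of the ECG band (Hz): baseline/P-T content,
#: low QRS, high QRS, high-frequency residue.  Clinically motivated and
#: fully configurable; the band boundaries are a package choice.
DEFAULT_EDGES_HZ = (0.5, 4.0, 12.0, 30.0, 60.0)


@dataclass(frozen=True)
class BandSpec:
    """K+1 ascending band-edge frequencies in Hz spanning (0, fs/2]."""

    edges_hz: tuple

    def __post_init__(self):
        e = tuple(float(v) for v in self.edges_hz)
        if len(e) < 2:
            raise ValueError("need at least two edges (one band)")
        if any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError(f"band edges must be strictly ascending, got {e}")
        if e[0] <= 0:
            raise ValueError("lowest edge must be > 0 (DC is carried by c0)")
        object.__setattr__(self, "edges_hz", e)

    @property
    def n_bands(self) -> int:
        return len(self.edges_hz) - 1

    def bin_edges(self, n: int, fs: float) -> list:
        """Map the Hz edges to DFT bin boundaries K_0 < K_1 < ... < K_K.

        bin = round(f * N / fs); the Nyquist bin (N even) belongs to the
        top band.  Raises if two edges collide on the same bin at this
        frame length.
        """
        if self.edges_hz[-1] > fs / 2 + 1e-9:
            raise ValueError(f"highest edge {self.edges_hz[-1]} Hz exceeds Nyquist {fs / 2} Hz")
        ks = [int(round(f * n / fs)) for f in self.edges_hz]
        # Lowest boundary K_0: bins strictly above K_0 are kept, so the
        # first band starts at bin K_0+1.  An edge rounding to bin 0 keeps
        # everything from bin 1 up.
        ks[0] = max(ks[0] - 1, 0) if ks[0] * fs / n >= self.edges_hz[0] else ks[0]
        for i, (a, b) in enumerate(zip(ks, ks[1:])):
            if b <= a:
                raise ValueError(
                    f"band {i + 1} ({self.edges_hz[i]}-{self.edges_hz[i + 1]} Hz) collapses: "
                    f"edges map to bins {a} and {b} at N={n}, fs={fs}"
                )
        ks[-1] = min(ks[-1], n // 2)
        return ks


@dataclass
class FibfSet:
    """Mean value plus the K FIBFs of one frame."""

    c0: float
    fibfs: np.ndarray  # shape (K, N)
    band_spec: BandSpec
    fs: float

    @property
    def n_bands(self) -> int:
        return self.fibfs.shape[0]

    def reconstruct(self) -> np.ndarray:
        return self.c0 + self.fibfs.sum(axis=0)

    def band_energies(self) -> np.ndarray:
        return (self.fibfs**2).sum(axis=1)


def default_band_edges(fs: float, n_bands: int = 4) -> BandSpec:
    """Default partition of (0, min(60, fs/2)] Hz into ``n_bands`` bands.

    For 4 bands this is the documented split 0.5-4-12-30-60 Hz (capped at
    Nyquist); otherwise the same range is split geometrically.
    """
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    top = min(60.0, fs / 2)
    if n_bands == 4 and top == 60.0:
        return BandSpec(DEFAULT_EDGES_HZ)
    edges = np.geomspace(0.5, top, n_bands + 1)
    return BandSpec(tuple(edges))


def decompose_fibf(frame: np.ndarray, band_spec: BandSpec, fs: float) -> FibfSet:
    """Decompose one frame into c0 plus K FIBFs via the DFT filter bank."""
    x = np.asarray(frame, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("frame must be a 1-D vector of length >= 2")
    n = x.size
    ks = band_spec.bin_edges(n, fs)
    X = np.fft.fft(x)
    scale = np.linalg.norm(x)
    fibfs = np.empty((band_spec.n_bands, n))
    for i in range(band_spec.n_bands):
        lo, hi = ks[i], ks[i + 1]
        mask = np.zeros(n, dtype=bool)
        mask[lo + 1 : hi + 1] = True
        # conjugate mirror; the Nyquist bin (n even, hi == n//2) is
        # self-conjugate and must not be re-selected
        mlo = n - hi if hi < (n + 1) // 2 or n % 2 == 1 else n - hi + 1
        mask[mlo : n - lo] = True
        y = np.fft.ifft(np.where(mask, X, 0.0))
        if scale > 0 and np.abs(y.imag).max() > 1e-9 * scale:
            raise AssertionError("non-negligible imaginary residue in FIBF")
        fibfs[i] = y.real
    return FibfSet(c0=float(x.mean()), fibfs=fibfs, band_spec=band_spec, fs=fs)


def full_tiling_spec(n: int, fs: float) -> BandSpec:
    """A BandSpec whose default-like bands exactly tile bins 1..N/2.

    Convenience for reconstruction/Parseval work: the top edge is forced
    to Nyquist and the bottom to just above DC.
    """
    lo = fs / n  # bin 1
    interior = [e for e in DEFAULT_EDGES_HZ[1:-1] if lo < e < fs / 2]
    return BandSpec(tuple([lo, *interior, fs / 2]))
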