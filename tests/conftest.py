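"""Shared fixtures and independent oracles.

The oracle functions here deliberately re-derive quantities by the most
direct route available (explicit peak scanning, raw FFT bin masking,
brute-force counting) so they stay independent of the library code they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

import ecgedge as ee


def oracle_peaks(x: np.ndarray, fs: float, threshold_frac: float = 0.6,
                 refractory_s: float = 0.3) -> list:
    """Naive R-peak detector: local maxima above 0.6*max with a 0.3 s
    refractory period, gated on a mean + 4*sigma significance floor so a
    trace with no spike structure yields no peaks.  Used only as a test
    oracle."""
    if x.max() <= 0:
        return []
    th = max(threshold_frac * x.max(), x.mean() + 4.0 * x.std())
    refr = int(refractory_s * fs)
    peaks, last = [], -(10**9)
    for i in range(1, len(x) - 1):
        if x[i] >= th and x[i] >= x[i - 1] and x[i] > x[i + 1] and i - last > refr:
            peaks.append(i)
            last = i
    return peaks


def oracle_band_energy(frame: np.ndarray, fs: float, lo_hz: float, hi_hz: float) -> float:
    """Band energy by direct FFT bin masking (Parseval), the reference for
    the filter-bank decomposition."""
    n = len(frame)
    X = np.fft.fft(frame)
    freqs = np.fft.fftfreq(n, d=1 / fs)
    mask = (np.abs(freqs) > lo_hz) & (np.abs(freqs) <= hi_hz)
    return float((np.abs(X[mask]) ** 2).sum() / n)


@pytest.fixture(scope="session")
def small_corpus():
    """A 90-signal synthetic corpus (in memory) shared across tests."""
    manifest = ee.generate_dataset(90, base_seed=7, write_signals=False)
    return list(ee.dataset_signals(manifest))


@pytest.fixture(scope="session")
def m1_features(small_corpus):
    return ee.extract_features(small_corpus, method=1)


@pytest.fixture(scope="session")
def m2_features(small_corpus):
    return ee.extract_features(small_corpus, method=2)
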