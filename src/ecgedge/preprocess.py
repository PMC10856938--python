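"""Acquisition-side signal conditioning.

Mirrors the front-end chain of the target device: down-sampling to 128 Hz,
a 60 Hz low-pass, redistribution of the amplitudes over the 12-bit ADC
range, and a running skewness/kurtosis validity monitor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps
from scipy import stats

from .core import EcgSignal

TARGET_FS = 128.0
LOWPASS_CUTOFF_HZ = 60.0
ADC_BITS = 12

# Validity-monitor defaults.  Lead-II ECG is right-skewed and leptokurtic
# (the R spikes), increasingly so at low heart rates where the spikes are
# sparse: skewness reaches ~4.3 and raw kurtosis ~28 at 30 bpm with this
# morphology.  The bands below admit the full 30-220 bpm range while
# flagging flat-lined input (kurtosis -> 0/1) and gross spike artifacts.
# Configurable assumptions.
DEFAULT_SKEW_RANGE = (-6.0, 6.0)
DEFAULT_KURT_RANGE = (1.2, 40.0)


@dataclass
class QualityReport:
    """Outcome of the skewness/kurtosis validity monitor."""

    skewness: float
    kurtosis: float
    passed: bool
    skew_range: tuple
    kurt_range: tuple


def resample_to(signal: EcgSignal, target_fs: float = TARGET_FS) -> EcgSignal:
    """Anti-aliased rational down-sampling to ``target_fs``.

    Only down-sampling is supported: the acquisition chain never raises
    the rate, and silent upsampling would fabricate bandwidth.
    """
    if signal.fs < target_fs:
        raise ValueError(
            f"upsampling requested ({signal.fs} Hz -> {target_fs} Hz); only down-sampling is supported"
        )
    if signal.fs == target_fs:
        return signal
    ratio = Fraction(target_fs).limit_denominator(10**6) / Fraction(signal.fs).limit_denominator(10**6)
    y = sps.resample_poly(signal.samples, ratio.numerator, ratio.denominator)
    n_out = int(round(signal.n_samples * target_fs / signal.fs))
    if y.size > n_out:
        y = y[:n_out]
    elif y.size < n_out:
        y = np.pad(y, (0, n_out - y.size))
    return signal.with_samples(y, fs=float(target_fs), bits=None)


def lowpass_60(signal: EcgSignal, cutoff_hz: float = LOWPASS_CUTOFF_HZ, order: int = 4) -> EcgSignal:
    """Zero-phase Butterworth low-pass at 60 Hz.

    Below fs = 2.5*cutoff the cutoff sits at or too close to Nyquist for
    a meaningful discrete-time response; the signal is returned unchanged
    with a warning (at the 128 Hz working rate 60 Hz is ~Nyquist, so the
    filter belongs before the down-sampler).
    """
    if signal.fs < 2.5 * cutoff_hz:
        warnings.warn(
            f"lowpass_60: fs={signal.fs} Hz puts the {cutoff_hz} Hz cutoff at/above Nyquist; passing through",
            stacklevel=2,
        )
        return signal
    sos = sps.butter(order, cutoff_hz, btype="low", fs=signal.fs, output="sos")
    y = sps.sosfiltfilt(sos, signal.samples)
    return signal.with_samples(y, bits=None)


def requantize_12bit(signal: EcgSignal, bits: int = ADC_BITS) -> EcgSignal:
    """Redistribute the amplitudes linearly over the full ADC range.

    min -> 0, max -> 2**bits - 1, round-half-up to integers.
    """
    x = signal.samples
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot requantize a constant signal (zero amplitude range)")
    full = 2**bits - 1
    q = np.floor((x - lo) / (hi - lo) * full + 0.5)
    return signal.with_samples(q, bits=bits)


def quality_check(
    signal: EcgSignal,
    skew_range: tuple = DEFAULT_SKEW_RANGE,
    kurt_range: tuple = DEFAULT_KURT_RANGE,
) -> QualityReport:
    """Skewness/kurtosis validity monitor over the full signal.

    Uses the population-moment definitions (1/N, raw non-excess
    kurtosis), matching the statistics the feature pipeline computes.
    Constant input has undefined standardized moments; both statistics
    are reported as 0 by convention and compared against the ranges.
    """
    x = signal.samples
    if x.size < 8:
        raise ValueError(f"quality_check needs at least 8 samples, got {x.size}")
    if np.ptp(x) == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    passed = (skew_range[0] <= skew <= skew_range[1]) and (kurt_range[0] <= kurt <= kurt_range[1])
    return QualityReport(skewness=skew, kurtosis=kurt, passed=passed,
                         skew_range=tuple(skew_range), kurt_range=tuple(kurt_range))


def preprocess_chain(signal: EcgSignal, target_fs: float = TARGET_FS, requantize: bool = False) -> EcgSignal:
    """Full conditioning chain: low-pass (at the native rate), down-sample,
    optional 12-bit redistribution."""
    out = lowpass_60(signal) if signal.fs > 2 * LOWPASS_CUTOFF_HZ else signal
    if out.fs > target_fs:
        out = resample_to(out, target_fs)
    if requantize:
        out = requantize_12bit(out)
    return out
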