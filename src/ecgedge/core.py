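"""Core container for a sampled single-lead ECG trace and CSV I/O.

The whole package operates on :class:`EcgSignal`: a real-valued sample
vector with its sampling rate, physical units and optional class label.
Signals are exchanged on disk as two-column CSV (``time_s, amplitude``),
which keeps every fixture human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Canonical class labels, in the fixed order used by the classifiers.
CLASS_LABELS = ("healthy", "infarcted", "noise")

#: Decision label emitted when no class clears the confidence threshold.
UNCERTAIN = "uncertain"


@dataclass
class EcgSignal:
    """A sampled single-lead ECG trace.

    Parameters
    ----------
    samples
        Real amplitude vector (float; integers in ``[0, 2**bits - 1]``
        once quantized).
    fs
        Sampling rate in Hz, strictly positive.
    units
        Amplitude units (free text, default millivolts).
    label
        Optional class label from :data:`CLASS_LABELS`.
    bits
        Quantization depth if the samples have been requantized.
    lead
        ECG lead name; this system analyzes lead II.
    meta
        Free-form metadata (e.g. beat times for synthetic signals).
    """

    samples: np.ndarray
    fs: float
    units: str = "mV"
    label: str | None = None
    bits: int | None = None
    lead: str = "II"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D vector")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASS_LABELS}")
        if self.bits is not None:
            hi = 2 ** self.bits - 1
            s = self.samples
            if not (np.all(s == np.round(s)) and s.min() >= 0 and s.max() <= hi):
                raise ValueError(f"bits={self.bits} set but samples are not integers in [0, {hi}]")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def with_samples(self, samples: np.ndarray, **changes) -> "EcgSignal":
        """Copy of this signal with new samples (metadata preserved)."""
        return replace(self, samples=np.asarray(samples, dtype=float), **changes)


def write_csv(signal: EcgSignal, path: str | Path) -> Path:
    """Write a signal as two-column CSV (``time_s, amplitude``)."""
    path = Path(path)
    pd.DataFrame({"time_s": signal.times, "amplitude": signal.samples}).to_csv(
        path, index=False, float_format="%.9g"
    )
    return path


def read_csv(path: str | Path, fs: float | None = None, label: str | None = None) -> EcgSignal:
    """Read a two-column CSV signal.

    The sampling rate is taken from ``fs`` when given, otherwise inferred
    as the reciprocal of the median time step.
    """
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    if "amplitude" not in cols:
        raise ValueError(f"{path}: expected an 'amplitude' column, found {list(df.columns)}")
    amp = df[cols["amplitude"]].to_numpy(dtype=float)
    if fs is None:
        if "time_s" not in cols:
            raise ValueError(f"{path}: no 'time_s' column and no fs given")
        dt = np.median(np.diff(df[cols["time_s"]].to_numpy(dtype=float)))
        if not dt > 0:
            raise ValueError(f"{path}: non-increasing time column")
        fs = 1.0 / dt
    return EcgSignal(samples=amp, fs=float(fs), label=label)
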