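"""Run the acquisition conditioning chain on a high-rate recording.

A 500 Hz trace is low-passed at 60 Hz, down-sampled to the 128 Hz
working rate, redistributed over the 12-bit ADC range, and screened by
the skewness/kurtosis validity monitor.
"""

import numpy as np

import ecgedge as ee

rng = np.random.default_rng(0)
t = np.arange(6 * 500) / 500
raw = ee.EcgSignal(np.sin(2 * np.pi * 8 * t) + 0.3 * np.sin(2 * np.pi * 120 * t)
                   + 0.05 * rng.standard_normal(t.size), fs=500)

clean = ee.preprocess_chain(raw, target_fs=128, requantize=True)
print(f"in : {raw.n_samples} samples @ {raw.fs} Hz")
print(f"out: {clean.n_samples} samples @ {clean.fs} Hz, {clean.bits}-bit, "
      f"range [{clean.samples.min():.0f}, {clean.samples.max():.0f}]")
# The 120 Hz interferer is gone; amplitudes span the full 0..4095 range.

q = ee.quality_check(clean)
print(f"quality: skew={q.skewness:.2f}, kurt={q.kurtosis:.2f}, pass={q.passed}")
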