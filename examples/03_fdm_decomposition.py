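"""Decompose one 2 s ECG frame into its Fourier Intrinsic Band Functions.

The zero-phase DFT filter bank splits the frame into four band-limited,
zero-mean, mutually orthogonal components; the mean plus their sum
reconstructs the frame to machine precision.
"""

import numpy as np

import ecgedge as ee
from ecgedge.fdm import full_tiling_spec

sig = ee.generate_ecg(ee.SyntheticConfig(label="healthy", duration_s=2, seed=3))
spec = ee.default_band_edges(sig.fs)
fset = ee.decompose_fibf(sig.samples, spec, sig.fs)

print(f"c0 (mean) = {fset.c0:.4f}")
total = fset.band_energies().sum()
for i in range(fset.n_bands):
    lo, hi = spec.edges_hz[i], spec.edges_hz[i + 1]
    e = fset.band_energies()[i]
    print(f"  band {i + 1} ({lo:>4.1f}-{hi:4.1f} Hz): energy {e:8.3f} ({100 * e / total:5.1f}%)")

# The clinical bands stop at 60 Hz; extend the partition over every DFT
# bin and the decomposition becomes an exact identity.
tiling = full_tiling_spec(sig.n_samples, sig.fs)
full = ee.decompose_fibf(sig.samples, tiling, sig.fs)
err = np.abs(full.reconstruct() - sig.samples).max()
print(f"reconstruction error under a full bin tiling: {err:.2e}")
# Most energy sits in the low bands (P/T waves and QRS fundamentals);
# the full-tiling reconstruction error is at float64 round-off.
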