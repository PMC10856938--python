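"""Method-1 features: 240 FIBF statistics for one 6 s decision window.

Twelve 2 s frames (one per 0.5 s), four FIBFs per frame, five statistics
per FIBF (energy, kurtosis, skewness, variance, spectral entropy).
"""

import ecgedge as ee

sig = ee.generate_ecg(ee.SyntheticConfig(label="infarcted", st_offset=0.2, seed=8))
fv = ee.method1_window_features(sig)
print(f"feature vector: {fv.values.size} values "
      f"({fv.n_frames} frames x {fv.n_bands} bands x {len(fv.stat_names)} statistics)")

# statistics of the last (most recent) frame, per band
last = fv.n_frames - 1
for band in range(fv.n_bands):
    vals = [fv.values[fv.index(last, band, s)] for s in range(5)]
    print(f"  band {band + 1}: " + ", ".join(
        f"{name}={v:7.3f}" for name, v in zip(fv.stat_names, vals)))
# Energies are bounded by the 256-sample frame length because each FIBF
# is max-abs normalized before the statistics are taken.
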