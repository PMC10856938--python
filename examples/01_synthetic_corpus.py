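"""Generate a small labeled ECG corpus and inspect its structure.

Each record is a 6 s lead-II trace at 128 Hz: healthy P-QRS-T beats,
infarcted beats (ST-segment offset, sometimes an inverted T wave), or a
cardiac-free noise mixture.  The split is stratified 80/20 per class.
"""

import ecgedge as ee

manifest = ee.generate_dataset(n_signals=30, base_seed=42, write_signals=False)
print("class counts:", manifest.class_counts)
for label in ee.CLASS_LABELS:
    n_test = sum(r["split"] == "test" and r["label"] == label for r in manifest.records)
    print(f"  {label:>9s}: {manifest.class_counts[label]} records, {n_test} held out")

sig, _ = next(ee.dataset_signals(manifest))
print(f"\nfirst record: {sig.label}, {sig.duration_s:.0f} s @ {sig.fs:.0f} Hz, "
      f"{len(sig.meta['beat_times_s'])} beats at "
      f"{[round(t, 2) for t in sig.meta['beat_times_s'][:4]]}... s")
# The beat times let downstream code locate the ST segment exactly.
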