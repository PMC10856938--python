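"""Run-profile handling.

A profile is a flat-ish dict carrying every numeric knob of the system —
sampling rate, cadences, band edges, spectrogram parameters, thresholds
and training hyper-parameters — so a complete configuration can live in
one YAML file.  :data:`REFERENCE_PROFILE` is the checked-in default: the
published operating point of the device (128 Hz, 6 s inference window,
0.5 s feature cadence, 4 FIBF bands, 1.4 s/0.2 s/-100 dB spectrogram,
240- and 1495-feature classifiers).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

REFERENCE_PROFILE = {
    "fs": 128.0,
    "lowpass_hz": 60.0,
    "adc_bits": 12,
    "quality": {"skew_range": [-6.0, 6.0], "kurt_range": [1.2, 40.0]},
    "window_s": 6.0,
    "update_s": 0.5,
    "inference_s": 6.0,
    "uncertain_threshold": 0.6,
    "method1": {
        "frame_s": 2.0,
        "band_edges_hz": [0.5, 4.0, 12.0, 30.0, 60.0],
        "norm_mode": "maxabs",
        "n_features": 240,
        "train": {"learning_rate": 8e-4, "epochs": 250, "validation_fraction": 0.2, "batch_size": 32},
    },
    "method2": {
        "frame_s": 1.4,
        "stride_s": 0.2,
        "nfft": 128,
        "noise_floor_db": -100.0,
        "n_features": 1495,
        "reshape_rows": 23,
        "train": {"learning_rate": 4e-4, "epochs": 400, "validation_fraction": 0.2, "batch_size": 32},
    },
    "dataset": {"n_signals": 612, "split_fraction": 0.8,
                "class_proportions": {"healthy": 0.34, "infarcted": 0.33, "noise": 0.33},
                "duration_s": 6.0, "st_offset": 0.2},
}


def default_profile() -> dict:
    return copy.deepcopy(REFERENCE_PROFILE)


def load_profile(path: str | Path | None = None) -> dict:
    """Load a YAML profile, overlaying the reference defaults."""
    profile = default_profile()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(profile, user)
    return profile


def save_profile(profile: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(profile, sort_keys=False))
    return path


def _deep_update(base: dict, overlay: dict) -> None:
    for k, v in overlay.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
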