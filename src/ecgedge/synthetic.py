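"""Synthetic single-lead ECG generator.

Emulates the three signal classes the detector is trained on:

* ``healthy`` — quasi-periodic P-QRS-T beats built from a fixed layout of
  five Gaussians (McSharry-style template) plus low-level noise;
* ``infarcted`` — the same template with an ST-segment amplitude offset
  between the QRS complex and the T wave and, optionally, an inverted
  T wave, the lead-II hallmarks of myocardial infarction;
* ``noise`` — baseline wander, broadband and powerline components only,
  with no cardiac template at all.

Everything is a pure function of its configuration and seed, so the
generated corpora are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import CLASS_LABELS, EcgSignal, write_csv

# Gaussian beat template: (time offset from R peak [s], width sigma [s],
# amplitude [mV, R normalized to 1]).  Fixed phase layout, amplitudes
# overridable through SyntheticConfig.wave_amplitudes.
WAVE_OFFSETS_S = {"P": -0.20, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.30}
WAVE_WIDTHS_S = {"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.010, "T": 0.050}
DEFAULT_WAVE_AMPLITUDES = {"P": 0.15, "Q": -0.10, "R": 1.0, "S": -0.15, "T": 0.30}

# ST span relative to the R peak: from the S-Gaussian center +20 ms to the
# T-Gaussian center -80 ms.  The infarction offset is applied exactly here,
# which makes its amplitude effect testable to machine precision.
ST_START_S = WAVE_OFFSETS_S["S"] + 0.020
ST_END_S = WAVE_OFFSETS_S["T"] - 0.080

#: Default additive-noise amplitudes (baseline wander, high-frequency,
#: powerline) for cardiac classes and for the noise class.
CARDIAC_NOISE_MIX = {"baseline": 0.05, "highfreq": 0.01, "powerline": 0.01}
NOISE_CLASS_MIX = {"baseline": 0.40, "highfreq": 0.30, "powerline": 0.20}

BASELINE_WANDER_HZ = 0.30
POWERLINE_HZ = 50.0
RR_JITTER_FRACTION = 0.02  # std of per-beat RR jitter, fraction of the RR


@dataclass
class SyntheticConfig:
    """Configuration for one synthetic record."""

    label: str = "healthy"
    duration_s: float = 6.0
    fs: float = 128.0
    heart_rate_bpm: float = 75.0
    st_offset: float = 0.0
    t_inversion: bool = False
    noise_mix: dict | None = None
    seed: int = 0
    wave_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_AMPLITUDES))

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown label {self.label!r}; expected one of {CLASS_LABELS}")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not 30 <= self.heart_rate_bpm <= 220:
            raise ValueError("heart_rate_bpm must lie in [30, 220]")
        if self.noise_mix is None:
            self.noise_mix = dict(
                NOISE_CLASS_MIX if self.label == "noise" else CARDIAC_NOISE_MIX
            )
        if any(v < 0 for v in self.noise_mix.values()):
            raise ValueError("noise_mix amplitudes must be non-negative")


def _beat_times(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered R-peak times covering the record (plus edge margins)."""
    rr = 60.0 / config.heart_rate_bpm
    times = []
    t = 0.5 * rr
    while t < config.duration_s + rr:
        times.append(t)
        t += rr * (1.0 + RR_JITTER_FRACTION * rng.standard_normal())
    return np.asarray(times)


def _cardiac_template(t: np.ndarray, beats: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    x = np.zeros_like(t)
    amps = dict(config.wave_amplitudes)
    if config.t_inversion:
        amps["T"] = -amps["T"]
    for beat in beats:
        for wave, amp in amps.items():
            mu = beat + WAVE_OFFSETS_S[wave]
            sig = WAVE_WIDTHS_S[wave]
            x += amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)
        if config.st_offset:
            x[st_span_mask_for_beat(t, beat)] += config.st_offset
    return x


def st_span_mask_for_beat(t: np.ndarray, beat_time: float) -> np.ndarray:
    """Boolean mask of the ST span of the beat centred at ``beat_time``."""
    return (t >= beat_time + ST_START_S) & (t <= beat_time + ST_END_S)


def st_span_mask(signal: EcgSignal) -> np.ndarray:
    """Union of the ST spans of all beats recorded in ``signal.meta``."""
    beats = np.asarray(signal.meta.get("beat_times_s", ()))
    t = signal.times
    mask = np.zeros(t.size, dtype=bool)
    for beat in beats:
        mask |= st_span_mask_for_beat(t, beat)
    return mask


def _noise(t: np.ndarray, mix: dict, rng: np.random.Generator) -> np.ndarray:
    n = np.zeros_like(t)
    phase_bw, phase_pl = rng.uniform(0, 2 * np.pi, size=2)
    n += mix.get("baseline", 0.0) * np.sin(2 * np.pi * BASELINE_WANDER_HZ * t + phase_bw)
    n += mix.get("powerline", 0.0) * np.sin(2 * np.pi * POWERLINE_HZ * t + phase_pl)
    n += mix.get("highfreq", 0.0) * rng.standard_normal(t.size)
    return n


def generate_ecg(config: SyntheticConfig) -> EcgSignal:
    """Generate one labeled synthetic ECG record.

    The random stream is consumed identically for ``healthy`` and
    ``infarcted`` configurations, so two records that differ only in
    ``st_offset``/``t_inversion`` share beat times and noise sample for
    sample — their difference is exactly the morphological change.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    beats = _beat_times(config, rng)
    if config.label == "noise":
        x = _noise(t, config.noise_mix, rng)
        beats = beats[:0]
    else:
        x = _cardiac_template(t, beats, config) + _noise(t, config.noise_mix, rng)
    visible = beats[(beats >= 0) & (beats < config.duration_s)]
    return EcgSignal(
        samples=x,
        fs=config.fs,
        label=config.label,
        meta={"beat_times_s": visible.tolist(), "seed": config.seed},
    )


# ---------------------------------------------------------------------------
# Dataset generation


@dataclass
class DatasetManifest:
    """Index of a generated corpus: one entry per record plus split counts.

    The train/test split is stratified per class; the test count of each
    class is ``round_half_up(class_count * (1 - split_fraction))``.
    """

    records: list  # of dicts: path, label, split, seed
    class_counts: dict
    split_fraction: float

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps(
                {
                    "records": self.records,
                    "class_counts": self.class_counts,
                    "split_fraction": self.split_fraction,
                    "split_rounding": "test = round-half-up(count * (1 - split_fraction)) per class",
                },
                indent=1,
            )
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DatasetManifest":
        d = json.loads(Path(path).read_text())
        return cls(d["records"], d["class_counts"], d["split_fraction"])


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _class_counts(n_signals: int, proportions: dict) -> dict:
    """Largest-remainder apportionment of n_signals across classes."""
    raw = {lab: n_signals * p for lab, p in proportions.items()}
    counts = {lab: int(np.floor(v)) for lab, v in raw.items()}
    short = n_signals - sum(counts.values())
    for lab in sorted(raw, key=lambda L: raw[L] - counts[L], reverse=True)[:short]:
        counts[lab] += 1
    return counts


def generate_dataset(
    n_signals: int,
    class_proportions: dict | None = None,
    split_fraction: float = 0.8,
    base_seed: int = 0,
    out_dir: str | Path = ".",
    duration_s: float = 6.0,
    fs: float = 128.0,
    st_offset: float = 0.2,
    write_signals: bool = True,
) -> DatasetManifest:
    """Generate a labeled corpus with a stratified train/test split.

    Each record draws its own heart rate (55–95 bpm) and, for infarcted
    records, a random T-wave inversion; the ST offset amplitude is fixed.
    Deterministic given ``base_seed``.
    """
    if n_signals < 3:
        raise ValueError("n_signals must be at least 3 (one per class)")
    if class_proportions is None:
        class_proportions = {lab: 1 / 3 for lab in CLASS_LABELS}
    total_p = sum(class_proportions.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {total_p}")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie in (0, 1)")

    counts = _class_counts(n_signals, class_proportions)
    if any(c < 1 for lab, c in counts.items() if class_proportions[lab] > 0):
        raise ValueError("n_signals too small to stratify across the requested classes")

    out_dir = Path(out_dir)
    if write_signals:
        out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(base_seed)
    records = []
    idx = 0
    for label in CLASS_LABELS:
        k = counts.get(label, 0)
        if k == 0:
            continue
        n_test = _round_half_up(k * (1.0 - split_fraction))
        for j in range(k):
            seed = int(master.integers(0, 2**31 - 1))
            hr = float(master.uniform(55, 95))
            t_inv = bool(master.random() < 0.5) if label == "infarcted" else False
            cfg = SyntheticConfig(
                label=label,
                duration_s=duration_s,
                fs=fs,
                heart_rate_bpm=hr,
                st_offset=st_offset if label == "infarcted" else 0.0,
                t_inversion=t_inv,
                seed=seed,
            )
            path = out_dir / f"{label}_{idx:05d}.csv"
            if write_signals:
                write_csv(generate_ecg(cfg), path)
            records.append(
                {
                    "path": str(path),
                    "label": label,
                    "split": "test" if j < n_test else "train",
                    "seed": seed,
                    "heart_rate_bpm": hr,
                    "t_inversion": t_inv,
                }
            )
            idx += 1

    manifest = DatasetManifest(records=records, class_counts=counts, split_fraction=split_fraction)
    if write_signals:
        manifest.to_json(out_dir / "manifest.json")
    return manifest


def dataset_signals(manifest: DatasetManifest, duration_s: float = 6.0, fs: float = 128.0,
                    st_offset: float = 0.2):
    """Regenerate the signals of a manifest in memory (no file I/O).

    Yields ``(EcgSignal, split)`` pairs in manifest order; used when the
    corpus is consumed immediately rather than round-tripped through CSV.
    """
    for rec in manifest.records:
        cfg = SyntheticConfig(
            label=rec["label"],
            duration_s=duration_s,
            fs=fs,
            heart_rate_bpm=rec["heart_rate_bpm"],
            st_offset=st_offset if rec["label"] == "infarcted" else 0.0,
            t_inversion=rec["t_inversion"],
            seed=rec["seed"],
        )
        yield generate_ecg(cfg), rec["split"]
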