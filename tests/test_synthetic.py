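"""Synthetic ECG generator: morphology, determinism, dataset splits."""

import numpy as np
import pytest

import ecgedge as ee
from ecgedge.synthetic import SyntheticConfig, _round_half_up

from conftest import oracle_peaks


class TestGenerateEcg:
    def test_healthy_beat_count_matches_heart_rate(self):
        sig = ee.generate_ecg(SyntheticConfig(label="healthy", duration_s=6, fs=128,
                                              heart_rate_bpm=60, seed=1))
        n_peaks = len(oracle_peaks(sig.samples, sig.fs))
        assert abs(n_peaks - 6) <= 1  # 1 Hz beat rate over 6 s, edge beats may fall off

    def test_sample_count_and_rate(self):
        sig = ee.generate_ecg(SyntheticConfig(duration_s=4.5, fs=200, seed=0))
        assert sig.n_samples == round(4.5 * 200)
        assert sig.fs == 200

    def test_st_offset_shifts_st_span_exactly(self):
        healthy = ee.generate_ecg(SyntheticConfig(label="healthy", st_offset=0.0, seed=3))
        infarct = ee.generate_ecg(SyntheticConfig(label="infarcted", st_offset=0.2, seed=3))
        mask = ee.st_span_mask(healthy)
        assert mask.any()
        diff = (infarct.samples - healthy.samples)[mask]
        assert abs(diff.mean() - 0.2) <= 0.02

    def test_t_inversion_flips_t_wave(self):
        up = ee.generate_ecg(SyntheticConfig(label="infarcted", seed=4, t_inversion=False))
        dn = ee.generate_ecg(SyntheticConfig(label="infarcted", seed=4, t_inversion=True))
        # the two traces differ only around the T wave, in opposite directions
        d = dn.samples - up.samples
        assert d.min() < -0.2 and d.max() < 1e-12

    def test_seeded_determinism(self):
        cfg = SyntheticConfig(label="infarcted", st_offset=0.15, t_inversion=True, seed=11)
        a = ee.generate_ecg(cfg)
        b = ee.generate_ecg(cfg)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_noise_class_has_no_cardiac_peaks(self):
        missing = 0
        for seed in range(50):
            sig = ee.generate_ecg(SyntheticConfig(label="noise", seed=seed))
            if len(oracle_peaks(sig.samples, sig.fs)) == 0:
                missing += 1
        assert missing >= 45  # no detected R-peaks in >= 90% of seeds

    def test_class_separability_of_st_statistic(self):
        healthy_means, infarct_means = [], []
        for seed in range(50):
            h = ee.generate_ecg(SyntheticConfig(label="healthy", seed=seed))
            i = ee.generate_ecg(SyntheticConfig(label="infarcted", st_offset=0.2, seed=seed))
            healthy_means.append(h.samples[ee.st_span_mask(h)].mean())
            infarct_means.append(i.samples[ee.st_span_mask(i)].mean())
        gap = abs(np.mean(infarct_means) - np.mean(healthy_means))
        assert gap >= 3 * np.std(healthy_means)

    @pytest.mark.parametrize("kwargs", [
        {"label": "ventricular"}, {"duration_s": 0}, {"fs": -1},
        {"heart_rate_bpm": 20}, {"noise_mix": {"baseline": -0.1}},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticConfig(**kwargs)


class TestGenerateDataset:
    def test_full_scale_counts(self, tmp_path):
        manifest = ee.generate_dataset(
            612, {"healthy": 1 / 3, "infarcted": 1 / 3, "noise": 1 / 3},
            split_fraction=0.8, base_seed=0, write_signals=False)
        assert len(manifest.records) == 612
        n_train = sum(r["split"] == "train" for r in manifest.records)
        n_test = sum(r["split"] == "test" for r in manifest.records)
        assert n_train + n_test == 612
        assert sum(manifest.class_counts.values()) == 612

    def test_single_class_exact_split(self):
        manifest = ee.generate_dataset(10, {"healthy": 1.0}, split_fraction=0.8,
                                       base_seed=1, write_signals=False)
        splits = [r["split"] for r in manifest.records]
        assert splits.count("train") == 8 and splits.count("test") == 2

    def test_per_class_round_half_up_rule(self):
        manifest = ee.generate_dataset(90, split_fraction=0.8, base_seed=2, write_signals=False)
        for label, count in manifest.class_counts.items():
            n_test = sum(r["split"] == "test" and r["label"] == label for r in manifest.records)
            assert n_test == _round_half_up(count * 0.2)

    def test_manifests_deterministic(self):
        a = ee.generate_dataset(30, base_seed=5, write_signals=False)
        b = ee.generate_dataset(30, base_seed=5, write_signals=False)
        assert a.records == b.records

    def test_written_corpus_roundtrips(self, tmp_path):
        manifest = ee.generate_dataset(6, base_seed=9, out_dir=tmp_path, duration_s=2.0)
        paths = [r["path"] for r in manifest.records]
        assert len(set(paths)) == len(paths)
        sig = ee.read_csv(paths[0])
        assert sig.n_samples == 256 and abs(sig.fs - 128) < 1e-6
        again = ee.DatasetManifest.from_json(tmp_path / "manifest.json")
        assert again.records == manifest.records

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ee.generate_dataset(9, {"healthy": 0.5, "infarcted": 0.6}, write_signals=False)
        with pytest.raises(ValueError):
            ee.generate_dataset(2, write_signals=False)
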