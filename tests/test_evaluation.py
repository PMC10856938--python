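"""Evaluation metrics with abstention: confusion tallies and the
precision/recall/F1/accuracy formulas checked against brute force."""

import numpy as np
import pytest

from ecgedge.core import CLASS_LABELS, UNCERTAIN
from ecgedge.evaluation import confusion, metrics_from_counts


def brute_force_metrics(true, decided, cls):
    """Counting oracle: walk the pairs and tally outcomes for one class."""
    tp = sum(1 for t, d in zip(true, decided) if t == cls and d == cls)
    fp = sum(1 for t, d in zip(true, decided) if t != cls and d == cls)
    fn = sum(1 for t, d in zip(true, decided) if t == cls and d != cls)
    tn = len(true) - tp - fp - fn
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return tp, fp, tn, fn, prec, rec, f1


class TestMetricsFromCounts:
    def test_worked_example(self):
        m = metrics_from_counts(tp=50, fp=10, tn=35, fn=5)
        assert m["precision"] == pytest.approx(50 / 60)
        assert m["recall"] == pytest.approx(50 / 55)
        assert m["f1"] == pytest.approx(2 * (50 / 60) * (50 / 55) / (50 / 60 + 50 / 55))
        assert m["accuracy"] == pytest.approx(0.85)

    def test_empty_positive_convention(self):
        m = metrics_from_counts(tp=0, fp=0, tn=10, fn=0)
        assert (m["precision"], m["recall"], m["f1"]) == (0, 0, 0)
        assert m["accuracy"] == 1.0

    @pytest.mark.parametrize("p", [0.25, 0.5, 1.0])
    def test_harmonic_mean_fixed_point(self, p):
        # precision == recall == p  =>  F1 == p; build counts realizing it
        tp = 100
        fp = fn = int(tp / p - tp)
        m = metrics_from_counts(tp, fp, 0, fn)
        assert m["f1"] == pytest.approx(p)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_counts(-1, 0, 0, 0)


class TestConfusion:
    def test_perfect_predictions(self):
        true = [lab for lab in CLASS_LABELS for _ in range(30)]
        rep = confusion(true, true)
        np.testing.assert_array_equal(rep.counts[:, :3], 30 * np.eye(3, dtype=int))
        assert rep.accuracy == 1.0
        assert all(rep.per_class[lab]["f1"] == 1.0 for lab in CLASS_LABELS)

    def test_toy_counts_example(self):
        true = ["healthy"] * 10 + ["infarcted"] * 10
        decided = ["healthy"] * 8 + ["infarcted"] * 2 + ["infarcted"] * 10
        rep = confusion(true, decided)
        h = rep.per_class["healthy"]
        assert h["precision"] == 1.0
        assert h["recall"] == pytest.approx(0.8)
        assert h["f1"] == pytest.approx(2 * 1.0 * 0.8 / 1.8)

    def test_all_uncertain(self):
        true = list(CLASS_LABELS) * 5
        rep = confusion(true, [UNCERTAIN] * len(true))
        assert rep.accuracy == 0.0
        assert all(rep.per_class[lab]["f1"] == 0.0 for lab in CLASS_LABELS)

    def test_row_percent_rows_sum_to_100(self):
        rng = np.random.default_rng(0)
        true = list(rng.choice(CLASS_LABELS, size=200))
        decided = list(rng.choice(CLASS_LABELS + (UNCERTAIN,), size=200))
        rep = confusion(true, decided)
        np.testing.assert_allclose(rep.row_percent.sum(axis=1), 100.0, atol=0.1)
        assert rep.counts.sum() == 200

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for trial in range(20):
            n = int(rng.integers(5, 200))
            true = list(rng.choice(CLASS_LABELS, size=n))
            decided = list(rng.choice(CLASS_LABELS + (UNCERTAIN,), size=n))
            rep = confusion(true, decided)
            diag = 0
            for cls in CLASS_LABELS:
                tp, fp, tn, fn, prec, rec, f1 = brute_force_metrics(true, decided, cls)
                got = rep.per_class[cls]
                assert (got["tp"], got["fp"], got["tn"], got["fn"]) == (tp, fp, tn, fn)
                assert got["precision"] == pytest.approx(prec)
                assert got["recall"] == pytest.approx(rec)
                assert got["f1"] == pytest.approx(f1)
                diag += tp
            assert rep.accuracy == pytest.approx(diag / n)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(3)
        true = list(rng.choice(CLASS_LABELS, size=300))
        decided = list(rng.choice(CLASS_LABELS + (UNCERTAIN,), size=300))
        rep = confusion(true, decided)
        for lab in CLASS_LABELS:
            m = rep.per_class[lab]
            if m["precision"] > 0 and m["recall"] > 0:
                assert min(m["precision"], m["recall"]) <= m["f1"] <= max(m["precision"], m["recall"])

    def test_uncertain_counts_as_fn_never_fp(self):
        true = ["healthy", "infarcted"]
        rep = confusion(true, [UNCERTAIN, UNCERTAIN])
        for lab in CLASS_LABELS[:2]:
            assert rep.per_class[lab]["fp"] == 0
            assert rep.per_class[lab]["fn"] == 1

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion([], [])
        with pytest.raises(ValueError):
            confusion(["healthy"], ["healthy", "noise"])
        with pytest.raises(ValueError, match="unknown true"):
            confusion([UNCERTAIN], ["healthy"])
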