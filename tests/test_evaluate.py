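"""Metrics, batch protocol, BMD categorisation, diagnostic reports."""

import json
import math

import numpy as np
import pytest

from osteotex import (
    ConfusionCounts,
    batch_evaluate_predictions,
    bmd_categorize,
    confusion,
    emit_report,
    metrics,
)


class TestConfusion:
    def test_perfect_agreement(self):
        labels = ["pos"] * 10 + ["neg"] * 10
        c = confusion(labels, labels, "pos")
        assert (c.TP, c.TN, c.FP, c.FN) == (10, 10, 0, 0)

    def test_all_predicted_positive(self):
        labels = ["pos"] * 10 + ["neg"] * 10
        preds = ["pos"] * 20
        c = confusion(preds, labels, "pos")
        assert (c.TP, c.FP, c.TN, c.FN) == (10, 10, 0, 0)

    def test_anti_identity(self):
        labels = ["pos", "neg", "pos", "neg"]
        preds = ["neg", "pos", "neg", "pos"]
        c = confusion(preds, labels, "pos")
        assert c.TP == 0 and c.TN == 0 and c.FP == 2 and c.FN == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion(["a"], ["a", "b"], "a")

    def test_unknown_positive_class_rejected(self):
        with pytest.raises(ValueError, match="positive_class"):
            confusion(["a"], ["a"], "z")

    def test_counts_total_matches_evaluated_images(self):
        c = confusion(["a", "b", "a"], ["b", "b", "a"], "a")
        assert c.total == 3


class TestMetrics:
    def test_reference_counts_give_exact_ratios(self):
        rep = metrics(ConfusionCounts(TP=9, TN=8, FP=1, FN=2))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.precision == pytest.approx(0.9)
        assert rep.sensitivity == pytest.approx(9 / 11)
        assert rep.specificity == pytest.approx(8 / 9)

    def test_perfect_counts_all_ones(self):
        rep = metrics(ConfusionCounts(TP=5, TN=5, FP=0, FN=0))
        assert (rep.accuracy, rep.precision, rep.sensitivity, rep.specificity) == (1, 1, 1, 1)

    def test_zero_denominator_flagged_not_zeroed(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            rep = metrics(ConfusionCounts(TP=0, TN=3, FP=0, FN=2))
        assert math.isnan(rep.precision)
        assert rep.sensitivity == 0.0

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))

    def test_class_symmetry_swaps_sensitivity_and_specificity(self):
        a = metrics(ConfusionCounts(TP=7, TN=5, FP=3, FN=1))
        b = metrics(ConfusionCounts(TP=5, TN=7, FP=1, FN=3))
        assert a.sensitivity == pytest.approx(b.specificity)
        assert a.specificity == pytest.approx(b.sensitivity)
        assert a.accuracy == pytest.approx(b.accuracy)


class TestBatchEvaluate:
    def _labels(self, n, rng):
        return list(rng.choice(["pos", "neg"], size=n))

    def test_200_images_give_10_rows_plus_average(self, rng):
        labels = self._labels(200, rng)
        preds = [l if rng.random() < 0.9 else ("neg" if l == "pos" else "pos") for l in labels]
        df = batch_evaluate_predictions(preds, labels, "pos", batch_size=20)
        assert len(df) == 11
        assert list(df["batch"][:10]) == list(range(1, 11))
        assert df["batch"].iloc[-1] == "average"

    def test_average_row_is_mean_of_batches(self, rng):
        labels = self._labels(200, rng)
        preds = [l if rng.random() < 0.8 else ("neg" if l == "pos" else "pos") for l in labels]
        df = batch_evaluate_predictions(preds, labels, "pos", batch_size=20)
        for m in ("accuracy", "precision", "sensitivity", "specificity"):
            assert df[m].iloc[-1] == pytest.approx(
                round(float(df[m][:10].mean(skipna=True)), 2), abs=1e-12
            )

    def test_perfect_classifier_rows_all_100(self, rng):
        labels = self._labels(60, rng)
        df = batch_evaluate_predictions(labels, labels, "pos", batch_size=20)
        assert (df["accuracy"] == 100.0).all()

    def test_within_batch_shuffle_invariance(self, rng):
        labels = self._labels(20, rng)
        preds = self._labels(20, rng)
        df1 = batch_evaluate_predictions(preds, labels, "pos", batch_size=20)
        order = rng.permutation(20)
        df2 = batch_evaluate_predictions(
            [preds[i] for i in order], [labels[i] for i in order], "pos", batch_size=20
        )
        for m in ("accuracy", "precision", "sensitivity", "specificity"):
            assert df1[m].iloc[0] == pytest.approx(df2[m].iloc[0], nan_ok=True)

    def test_partial_final_batch_flagged_by_size(self, rng):
        labels = self._labels(25, rng)
        df = batch_evaluate_predictions(labels, labels, "pos", batch_size=20)
        assert list(df["n_images"][:2]) == [20, 5]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            batch_evaluate_predictions([], [], "pos")


class TestBMDCategorize:
    @pytest.mark.parametrize(
        "bmd,expected",
        [
            (900.0, "normal"),
            (834.0, "normal"),
            (833.0, "osteopenia"),
            (700.0, "osteopenia"),
            (648.0, "osteopenia"),
            (647.9, "osteoporotic"),
            (600.0, "osteoporotic"),
        ],
    )
    def test_threshold_rule(self, bmd, expected):
        assert bmd_categorize(bmd) == expected

    def test_monotone_over_grid(self):
        severity = {"normal": 0, "osteopenia": 1, "osteoporotic": 2}
        grid = np.arange(100.0, 1500.0, 1.0)
        cats = [severity[bmd_categorize(v)] for v in grid]
        assert all(a >= b for a, b in zip(cats, cats[1:]))

    @pytest.mark.parametrize("bad", [0.0, -5.0, float("nan"), float("inf")])
    def test_invalid_bmd_rejected(self, bad):
        with pytest.raises(ValueError):
            bmd_categorize(bad)


class TestEmitReport:
    def test_roundtrip_through_json(self, tmp_path):
        path = tmp_path / "report.json"
        report = emit_report(
            "osteoporotic",
            {"normal": 0.1, "osteoporotic": 0.9},
            bmd=620.0,
            metadata={"channels": ["natural", "bilateral", "residual", "hgze_map"]},
            path=path,
        )
        loaded = json.loads(path.read_text())
        assert loaded == report
        assert loaded["bmd_category"] == "osteoporotic"
        assert path.with_suffix(".txt").exists()

    def test_channel_provenance_recorded_in_order(self):
        channels = ["natural", "bilateral", "residual", "hgze_map"]
        report = emit_report(
            "normal", {"normal": 0.8, "osteoporotic": 0.2},
            metadata={"channels": channels},
        )
        assert report["metadata"]["channels"] == channels

    def test_prediction_must_be_among_probabilities(self):
        with pytest.raises(ValueError):
            emit_report("weird", {"normal": 1.0})
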