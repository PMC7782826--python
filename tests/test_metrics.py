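"""Gross AUPRC/AUROC, overlap metrics and dataset evaluation."""

import numpy as np
import pytest

from sleepseg.errors import PairingError, ParameterError, UndefinedMetricError
from sleepseg.metrics import (
    evaluate_dataset,
    gross_auprc,
    gross_auroc,
    segmentation_overlap,
)
from sleepseg.training import PredictionTrack


def _labels(rng, n, frac):
    return (rng.random(n) < frac).astype(np.int8)


class TestGrossAUPRC:
    def test_perfect_separation_scores_one(self):
        y = np.array([1, 1, 0, 0, -1], np.int8)
        p = np.array([1.0, 1.0, 0.0, 0.0, 0.3])
        assert gross_auprc([y], [p]) == 1.0

    def test_constant_predictor_equals_prevalence_exactly(self, rng):
        for n, k in [(1000, 72), (500, 13), (200, 57)]:
            y = np.zeros(n, np.int8)
            y[:k] = 1
            p = np.full(n, 0.3)
            assert gross_auprc([y], [p]) == k / n

    def test_nonscored_samples_excluded(self, rng):
        y = np.array([1, 0, -1], np.int8)
        p = np.array([0.9, 0.2, 0.99])
        assert gross_auprc([y], [p]) == gross_auprc([y[:2]], [p[:2]])

    def test_no_arousal_samples_undefined(self):
        with pytest.raises(UndefinedMetricError):
            gross_auprc([np.zeros(10, np.int8)], [np.zeros(10)])

    def test_matches_exhaustive_threshold_oracle(self, rng):
        from sklearn.metrics import precision_recall_curve

        for _ in range(30):
            n = int(rng.integers(200, 2001))
            y = _labels(rng, n, rng.uniform(0.05, 0.3))
            if y.sum() == 0:
                continue
            p = rng.integers(0, 1001, n) / 1000.0
            prec, rec, _ = precision_recall_curve(y, p)
            oracle = -np.sum(np.diff(rec) * np.asarray(prec)[:-1])
            assert abs(gross_auprc([y], [p]) - oracle) < 2e-3


class TestGrossAUROC:
    def test_perfect_constant_and_antiperfect(self):
        y = np.array([1, 1, 0, 0], np.int8)
        perfect = np.array([0.9, 0.8, 0.2, 0.1])
        assert gross_auroc([y], [perfect]) == 1.0
        assert gross_auroc([y], [np.full(4, 0.4)]) == 0.5
        assert gross_auroc([y], [1.0 - perfect]) == 0.0

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            gross_auroc([np.ones(5, np.int8)], [np.ones(5) * 0.5])

    def test_matches_sklearn_on_grid_valued_predictions(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(200, 2001))
            y = _labels(rng, n, 0.2)
            p = rng.integers(0, 1001, n) / 1000.0
            assert abs(gross_auroc([y], [p]) - roc_auc_score(y, p)) < 2e-3


class TestPoolingEquivalence:
    def test_grouping_into_records_is_irrelevant(self, rng):
        y = _labels(rng, 600, 0.15)
        p = rng.random(600)
        joint_pr = gross_auprc([y[:200], y[200:]], [p[:200], p[200:]])
        assert joint_pr == gross_auprc([y], [p])
        joint_roc = gross_auroc([y[:200], y[200:]], [p[:200], p[200:]])
        assert joint_roc == gross_auroc([y], [p])

    def test_record_order_is_irrelevant(self, rng):
        ys = [_labels(rng, 100, 0.2) for _ in range(3)]
        ps = [rng.random(100) for _ in range(3)]
        assert gross_auprc(ys, ps) == gross_auprc(ys[::-1], ps[::-1])


class TestRankInvariance:
    def test_monotone_transforms_preserve_metrics(self):
        # dense instances: discretization error of the 1/1000 grid stays
        # within 2e-3 when the transform preserves the spread of values
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = _labels(rng, 5000, 0.2)
            p = rng.random(5000)
            base_pr, base_roc = gross_auprc([y], [p]), gross_auroc([y], [p])
            for f in (np.sqrt, lambda q: q ** 2, lambda q: 0.1 + 0.8 * q):
                assert abs(gross_auprc([y], [f(p)]) - base_pr) < 2e-3
                assert abs(gross_auroc([y], [f(p)]) - base_roc) < 2e-3


class TestSegmentationOverlap:
    def test_identical_masks(self):
        y = np.array([1, 0, 1, -1], np.int8)
        p = np.array([0.9, 0.1, 0.8, 0.5])
        assert segmentation_overlap(y, p) == (1.0, 1.0)

    def test_disjoint_masks(self):
        y = np.array([1, 1, 0, 0], np.int8)
        p = np.array([0.1, 0.2, 0.9, 0.8])
        assert segmentation_overlap(y, p) == (0.0, 0.0)

    def test_jaccard_dice_identity(self, rng):
        for _ in range(20):
            y = _labels(rng, 200, 0.3)
            p = rng.random(200)
            dice, jaccard = segmentation_overlap(y, p)
            if dice > 0:
                assert abs(jaccard - dice / (2.0 - dice)) < 1e-12

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ParameterError):
            segmentation_overlap(np.array([1, 0], np.int8),
                                 np.array([0.5, 0.5]), threshold=1.5)


class TestEvaluateDataset:
    def test_identical_records_gross_equals_per_record(self, rng):
        y = _labels(rng, 300, 0.2)
        p = rng.random(300)
        report = evaluate_dataset([y, y], [p, p])
        assert report.gross_auprc == report.per_record["auprc"].iloc[0]
        assert report.gross_auroc == report.per_record["auroc"].iloc[0]

    def test_zero_arousal_record_gets_absent_auprc(self, rng):
        good = _labels(rng, 200, 0.3)
        empty = np.zeros(200, np.int8)
        report = evaluate_dataset([good, empty],
                                  [rng.random(200), rng.random(200)])
        assert np.isnan(report.per_record["auprc"].iloc[1])

    def test_prevalence_matches_generator_bookkeeping(self, medium_dataset):
        items, manifest, config = medium_dataset
        labels = [it[1] for it in items]
        preds = [np.full(len(lab), 0.4) for lab in labels]
        report = evaluate_dataset(labels, preds)
        assert abs(report.prevalence - config.arousal_rate) < 0.01
        # constant predictor: gross AUPRC equals pooled prevalence exactly
        assert report.gross_auprc == report.prevalence

    def test_record_id_mismatch_raises(self, rng):
        y = PredictionTrack(rng.random(10), record_id="a")
        from sleepseg.records import LabelTrack

        lab = LabelTrack(np.ones(10, np.int8))
        lab.record_id = "b"
        with pytest.raises(PairingError):
            evaluate_dataset([lab], [y])

    def test_report_exports(self, rng, tmp_path):
        y = _labels(rng, 300, 0.2)
        report = evaluate_dataset([y], [rng.random(300)])
        report.to_json(tmp_path / "report.json")
        report.to_csv(tmp_path / "per_record.csv")
        assert (tmp_path / "report.json").stat().st_size > 0
        assert (tmp_path / "per_record.csv").stat().st_size > 0
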