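"""Confusion matrices, accuracy reports, Cohen's d, dataset summaries,
and detection precision/recall."""

import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytostage.evaluation import (
    ConfusionMatrix,
    accuracy_report,
    cohens_d,
    confusion_matrix,
    dataset_summary,
    detection_prf,
)
from cytostage.staging import STAGES
from cytostage.yolo_io import BoundingBox, CellAnnotation, CellClass, LabeledImageSet

D, P, E, M = STAGES


class TestConfusionMatrix:
    def test_hand_tally(self):
        cm = confusion_matrix([D, D, P, E], [D, M, P, P], STAGES)
        assert cm.counts[0, 0] == 1 and cm.counts[0, 3] == 1
        assert cm.normalized[0].tolist() == [0.5, 0.0, 0.0, 0.5]
        assert cm.total == 4

    def test_perfect_predictions_give_identity(self):
        cm = confusion_matrix(list(STAGES), list(STAGES), STAGES)
        assert np.array_equal(cm.normalized, np.eye(4))

    def test_errors(self):
        with pytest.raises(ValueError, match="length mismatch"):
            confusion_matrix([D], [D, P], STAGES)
        with pytest.raises(ValueError, match="unknown"):
            confusion_matrix([D], ["Anestrus"], STAGES)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.sampled_from(STAGES), st.sampled_from(STAGES)), max_size=60),
           st.randoms(use_true_random=False))
    def test_rows_normalize_and_permutation_invariance(self, pairs, rnd):
        true = [t for t, _ in pairs]
        pred = [p for _, p in pairs]
        cm = confusion_matrix(true, pred, STAGES)
        for row in cm.normalized:
            assert row.sum() == pytest.approx(1.0) or row.sum() == 0.0
        shuffled = pairs[:]
        rnd.shuffle(shuffled)
        cm_shuffled = confusion_matrix([t for t, _ in shuffled], [p for _, p in shuffled], STAGES)
        assert np.array_equal(cm.counts, cm_shuffled.counts)


class TestAccuracyReport:
    def test_identity_matrix(self):
        report = accuracy_report(confusion_matrix(list(STAGES), list(STAGES), STAGES))
        assert report.per_class_accuracy == (1.0, 1.0, 1.0, 1.0)
        assert report.mean_accuracy == 1.0 and report.overall_accuracy == 1.0

    def test_unweighted_mean_of_per_class_accuracies(self):
        # two classes, one perfect and one always wrong, unequal sizes
        cm = ConfusionMatrix(labels=("a", "b"), counts=np.array([[30, 0], [10, 0]]))
        report = accuracy_report(cm)
        assert report.per_class_accuracy == (1.0, 0.0)
        assert report.mean_accuracy == 0.5
        assert report.overall_accuracy == 0.75

    def test_unweighted_vs_weighted_mean_differ(self):
        """Per-stage accuracies 85/70/92/74 on 100/100/100/50 images: the
        unweighted mean is 80.25%, while trace/total weights the smaller
        metestrus set up to 81.1%."""
        sizes = {D: 100, P: 100, E: 100, M: 50}
        rates = {D: 0.85, P: 0.70, E: 0.92, M: 0.74}
        counts = np.zeros((4, 4), dtype=int)
        for i, stage in enumerate(STAGES):
            diag = round(rates[stage] * sizes[stage])
            counts[i, i] = diag
            counts[i, (i + 1) % 4] = sizes[stage] - diag
        report = accuracy_report(ConfusionMatrix(labels=STAGES, counts=counts))
        assert report.mean_accuracy == pytest.approx(0.8025)
        assert report.overall_accuracy == pytest.approx(284 / 350)


class TestCohensD:
    def test_identical_groups(self):
        assert cohens_d([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]).d == 0.0

    def test_worked_example(self):
        # means 85 and 65, pooled sd sqrt(50) -> d = 20/7.0711
        effect = cohens_d([80.0, 90.0], [60.0, 70.0])
        assert effect.d == pytest.approx(20 / math.sqrt(50), abs=1e-9)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 4.0], [3.0, 3.5, 5.0]
        assert cohens_d(a, b).d == pytest.approx(-cohens_d(b, a).d, abs=1e-12)

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(17)
        a = rng.normal(10, 2, 25)
        b = rng.normal(8, 3, 18)
        ours = cohens_d(a, b).d
        theirs = pingouin.compute_effsize(a, b, eftype="cohen")
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [2.0, 3.0])


def _set_with(counts_per_class):
    anns = []
    for cls, n in zip(CellClass, counts_per_class):
        anns.extend(
            CellAnnotation(cls, BoundingBox(0.5, 0.5, 0.1, 0.1)) for _ in range(n)
        )
    return LabeledImageSet(entries=[(Path("img.png"), anns)])


class TestDatasetSummary:
    def test_totals_across_sets(self):
        summary = dataset_summary(
            {"train": _set_with((9, 12, 4)), "validation": _set_with((2, 1, 1))}
        )
        assert summary.loc["Leukocyte", "Total"] == 11
        assert summary.loc["Cornified", "Total"] == 13
        assert summary.loc["Nucleated", "Total"] == 5
        assert summary.loc["All", "Total"] == 29
        assert (summary["Total"] == summary[["train", "validation"]].sum(axis=1)).all()

    def test_empty_sets(self):
        summary = dataset_summary({"empty": _set_with((0, 0, 0))})
        assert (summary["Total"] == 0).all()


def _box(x, y, w=0.1, h=0.1):
    return BoundingBox(x, y, w, h)


class TestDetectionPRF:
    def test_perfect_predictions(self):
        truth = [
            CellAnnotation(CellClass.LEUKOCYTE, _box(0.2, 0.2)),
            CellAnnotation(CellClass.CORNIFIED, _box(0.6, 0.6)),
        ]
        pred = [CellAnnotation(a.cell_class, a.box, 0.9) for a in truth]
        prf = detection_prf(truth, pred)
        assert prf.loc["micro", "precision"] == 1.0
        assert prf.loc["micro", "recall"] == 1.0
        assert prf.loc["micro", "f1"] == 1.0

    def test_no_predictions_flagged_undefined(self):
        truth = [CellAnnotation(CellClass.LEUKOCYTE, _box(0.2, 0.2))]
        prf = detection_prf(truth, [])
        assert prf.loc["Leukocyte", "recall"] == 0.0
        assert prf.loc["Leukocyte", "precision"] == 0.0
        assert bool(prf.loc["Leukocyte", "undefined"]) is True

    def test_duplicate_predictions_count_one_tp_one_fp(self):
        truth = [CellAnnotation(CellClass.NUCLEATED, _box(0.5, 0.5))]
        pred = [
            CellAnnotation(CellClass.NUCLEATED, _box(0.5, 0.5), 0.9),
            CellAnnotation(CellClass.NUCLEATED, _box(0.51, 0.5), 0.8),
        ]
        prf = detection_prf(truth, pred)
        assert prf.loc["Nucleated", "tp"] == 1
        assert prf.loc["Nucleated", "fp"] == 1
        assert prf.loc["Nucleated", "fn"] == 0

    def test_class_mismatch_is_not_a_match(self):
        truth = [CellAnnotation(CellClass.NUCLEATED, _box(0.5, 0.5))]
        pred = [CellAnnotation(CellClass.CORNIFIED, _box(0.5, 0.5), 0.9)]
        prf = detection_prf(truth, pred)
        assert prf.loc["micro", "tp"] == 0

    def test_iou_threshold_validated(self):
        with pytest.raises(ValueError):
            detection_prf([], [], iou_min=0.0)
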