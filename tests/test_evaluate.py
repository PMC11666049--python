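import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spindlebox.evaluate import (
    Detection,
    PRCurve,
    aggregate_folds,
    average_precision,
    evaluate_detections,
    iou,
    kfold_split,
    leave_subject_out_split,
    match_detections,
    mean_average_precision,
    precision_recall,
    round_percent,
    split_dataset,
)
from spindlebox.render import BoundingBox
from spindlebox.signal_io import EventClass

from .oracles import ap_fine_grid_oracle, box, greedy_match_oracle, random_box

SP = EventClass.SPINDLE


finite_box = st.builds(
    box,
    st.floats(0, 500), st.floats(0, 500),
    st.floats(0.1, 300), st.floats(0.1, 300),
)


class TestIoU:
    @settings(derandomize=True, deadline=None)
    @given(a=finite_box, b=finite_box)
    def test_bounded_and_symmetric(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0
        assert v == pytest.approx(iou(b, a))
    def test_identical_boxes(self):
        b = box(3, 4, 10, 20)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(box(0, 0, 10, 10), box(50, 50, 10, 10)) == 0.0

    def test_half_overlap_lattice(self):
        # intersection 50 px, union 150 px
        assert iou(box(0, 0, 10, 10), box(5, 0, 10, 10)) == pytest.approx(1 / 3)

    def test_symmetry(self, rng):
        for _ in range(100):
            a, b = random_box(rng), random_box(rng)
            assert iou(a, b) == pytest.approx(iou(b, a))


class TestMatching:
    def test_exact_hit(self):
        truth = box(10, 10, 20, 20)
        det = [Detection(truth, SP, 0.9, "im0")]
        flags, fn = match_detections(det, {"im0": [truth]}, 0.5)
        assert (flags, fn) == ([True], 0)

    def test_duplicate_detections_one_tp(self):
        truth = box(10, 10, 20, 20)
        dets = [
            Detection(box(11, 10, 20, 20), SP, 0.6, "im0"),
            Detection(box(10, 10, 20, 20), SP, 0.9, "im0"),
        ]
        flags, fn = match_detections(dets, {"im0": [truth]}, 0.5)
        # confidence order: 0.9 first (TP), 0.6 second (truth taken -> FP)
        assert flags == [True, False]
        assert fn == 0

    def test_matches_brute_force_on_random_layouts(self, rng):
        for trial in range(500):
            n_det = int(rng.integers(0, 5))
            n_truth = int(rng.integers(0, 5))
            truths = {"im": [random_box(rng) for _ in range(n_truth)]}
            dets = [
                Detection(random_box(rng), SP, float(rng.uniform()), "im")
                for _ in range(n_det)
            ]
            t = float(rng.choice([0.3, 0.5, 0.7]))
            assert match_detections(dets, truths, t) == greedy_match_oracle(
                dets, truths, t
            )

    def test_tp_count_never_rises_with_threshold(self, rng):
        truths = {"im": [random_box(rng) for _ in range(6)]}
        dets = [Detection(random_box(rng), SP, float(rng.uniform()), "im")
                for _ in range(10)]
        tps = [
            sum(match_detections(dets, truths, t)[0])
            for t in (0.5, 0.6, 0.7)
        ]
        assert tps == sorted(tps, reverse=True)


class TestPrecisionRecall:
    def test_single_tp_of_two_truths(self):
        curve = precision_recall([True], 2)
        assert curve.recall.tolist() == [0.5]
        assert curve.precision.tolist() == [1.0]

    def test_tp_then_fp(self):
        curve = precision_recall([True, False], 1)
        assert curve.recall.tolist() == [1.0, 1.0]
        assert curve.precision.tolist() == [1.0, 0.5]

    def test_no_truths_gives_empty_sentinel(self):
        assert precision_recall([False, False], 0).empty

    def test_prefix_oracle_on_random_flags(self, rng):
        for _ in range(10):
            flags = rng.uniform(size=20) < 0.4
            n_truths = int(flags.sum() + rng.integers(0, 5))
            if n_truths == 0:
                continue
            curve = precision_recall(flags.tolist(), n_truths)
            for k in range(1, flags.size + 1):
                tp = int(flags[:k].sum())
                assert curve.recall[k - 1] == pytest.approx(tp / n_truths)
                assert curve.precision[k - 1] == pytest.approx(tp / k)


class TestAveragePrecision:
    def test_perfect_single_detection(self):
        assert average_precision(precision_recall([True], 1)) == pytest.approx(100.0)

    def test_envelope_rescues_trailing_fp(self):
        curve = precision_recall([True, False], 1)
        assert average_precision(curve) == pytest.approx(100.0)

    def test_matches_fine_grid_oracle(self, rng):
        for _ in range(25):
            flags = (rng.uniform(size=20) < 0.5).tolist()
            n_truths = max(int(sum(flags) + rng.integers(0, 4)), 1)
            curve = precision_recall(flags, n_truths)
            if curve.empty:
                continue
            ap = average_precision(curve, "all_points")
            assert abs(ap / 100.0 - ap_fine_grid_oracle(curve)) <= 1e-6

    def test_all_points_at_least_unenveloped_area(self, rng):
        for _ in range(20):
            flags = (rng.uniform(size=15) < 0.5).tolist()
            if not any(flags):
                continue
            curve = precision_recall(flags, sum(flags))
            r = np.concatenate([[0.0], curve.recall])
            raw_area = 100.0 * float(np.sum(np.diff(r) * curve.precision))
            assert average_precision(curve, "all_points") >= raw_area - 1e-12

    def test_confidence_rescaling_invariance(self, rng):
        truths = {"im": [random_box(rng) for _ in range(5)]}
        dets = [Detection(random_box(rng), SP, float(c), "im")
                for c in rng.uniform(0.2, 0.8, size=8)]
        rescaled = [Detection(d.box, SP, d.confidence * 0.5 + 0.1, d.image_id)
                    for d in dets]
        for t in (0.3, 0.5):
            f1, _ = match_detections(dets, truths, t)
            f2, _ = match_detections(rescaled, truths, t)
            n = len(truths["im"])
            assert average_precision(precision_recall(f1, n)) == pytest.approx(
                average_precision(precision_recall(f2, n))
            )

    def test_points_101_close_to_all_points(self):
        curve = precision_recall([True, False, True, True, False], 4)
        a = average_precision(curve, "all_points")
        b = average_precision(curve, "points_101")
        assert abs(a - b) < 5.0  # same envelope, coarser grid

    def test_empty_curve_scores_zero(self):
        assert average_precision(PRCurve(np.empty(0), np.empty(0))) == 0.0


class TestMeanAveragePrecision:
    def test_fold1_cells_from_cross_validation_table(self):
        cells = (98.7, 96.3, 97.8, 91.0, 98.0, 87.5)
        assert round_percent(mean_average_precision(dict(enumerate(cells)))) == 94.9

    def test_fold4_cells_from_cross_validation_table(self):
        cells = (96.1, 100.0, 93.4, 99.4, 96.0, 98.7)
        assert round_percent(mean_average_precision(dict(enumerate(cells)))) == 97.3

    def test_constant_table(self):
        table = {SP: {0.5: 88.0, 0.6: 88.0}, EventClass.KCOMPLEX: {0.5: 88.0}}
        assert mean_average_precision(table) == pytest.approx(88.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            mean_average_precision({})

    def test_perfect_detector_maps_100(self, rng):
        truths = {f"im{i}": [random_box(rng) for _ in range(3)] for i in range(4)}
        dets = [
            Detection(b, SP, 1.0, img)
            for img, boxes in truths.items()
            for b in boxes
        ]
        report = evaluate_detections(dets, truths)
        for t in (0.5, 0.6, 0.7):
            assert report.ap[SP][t] == pytest.approx(100.0)


class TestSplits:
    def test_fraction_sizes(self):
        parts = split_dataset(100, (0.8, 0.1, 0.1), seed=0)
        assert [len(p) for p in parts] == [80, 10, 10]
        assert sorted(np.concatenate(parts).tolist()) == list(range(100))

    @pytest.mark.parametrize("fracs", [(0.5, 0.1, 0.4), (0.6, 0.1, 0.3)])
    def test_uneven_fractions_partition_exactly(self, fracs):
        parts = split_dataset(103, fracs, seed=1)
        assert sum(len(p) for p in parts) == 103
        assert sorted(np.concatenate(parts).tolist()) == list(range(103))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(10, (0.5, 0.1))

    def test_kfold_sizes_and_exhaustiveness(self):
        folds = kfold_split(103, k=5, seed=0)
        test_sizes = sorted(len(te) for _, te in folds)
        assert test_sizes == [20, 20, 21, 21, 21]
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(103))
        for train, test in folds:
            assert not set(train.tolist()) & set(test.tolist())

    def test_leave_subject_out(self):
        subjects = ["A", "A", "B", "B", "B", "C"]
        folds = leave_subject_out_split(subjects, seed=0)
        assert len(folds) == 3
        for train, test in folds:
            test_subjects = {subjects[i] for i in test}
            train_subjects = {subjects[i] for i in train}
            assert len(test_subjects) == 1
            assert not test_subjects & train_subjects

    def test_leave_subject_out_needs_two_subjects(self):
        with pytest.raises(ValueError):
            leave_subject_out_split(["A", "A"])


class TestFoldAggregation:
    def test_ss_iou50_row(self):
        mean, sd = aggregate_folds((98.7, 96.2, 99.0, 96.1, 99.4))
        assert (mean, sd) == (97.9, 1.4)

    def test_kc_iou50_row_needs_population_divisor(self):
        folds = (96.3, 100.0, 98.1, 100.0, 94.2)
        mean, sd = aggregate_folds(folds)
        assert (mean, sd) == (97.7, 2.2)
        # the sample (N-1) divisor would give 2.5, not the tabulated 2.2
        assert round_percent(float(np.std(folds, ddof=1))) == 2.5

    def test_identical_folds_zero_sd(self):
        assert aggregate_folds((88.8, 88.8, 88.8)) == (88.8, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_folds(())
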