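"""Dice/IoU/Hausdorff against brute-force oracles and worked examples."""

import math

import numpy as np
import pytest

from wsiseg.metrics import (ConfusionAreas, confusion_areas, dice,
                            directed_hausdorff, evaluate_dataset, hausdorff,
                            iou, points_of_class)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def tally_oracle(pred, gt, ignore, c):
    """Triple-loop pixel tally."""
    tp = fp = fn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if ignore is not None and ignore[i, j]:
                continue
            p, g = pred[i, j] == c, gt[i, j] == c
            tp += p and g
            fp += p and not g
            fn += g and not p
    return tp, fp, fn


def hausdorff_oracle(a, b):
    """O(|A||B|) double loop, undirected."""
    def directed(u, v):
        return max(min(math.dist(p, q) for q in v) for p in u)
    return max(directed(a, b), directed(b, a))


# ---------------------------------------------------------------------------
# Confusion areas / Dice / IoU
# ---------------------------------------------------------------------------

class TestConfusionAreas:
    def test_perfect_prediction(self, rng):
        gt = rng.integers(0, 3, (16, 16))
        for c in range(3):
            areas = confusion_areas(gt, gt, None, c)
            assert (areas.fp, areas.fn) == (0, 0)
            assert areas.tp == (gt == c).sum()

    def test_disjoint_regions_have_zero_tp(self):
        pred = np.zeros((8, 8), int)
        gt = np.ones((8, 8), int)
        assert confusion_areas(pred, gt, None, 0).tp == 0
        assert confusion_areas(pred, gt, None, 1).tp == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_tally(self, seed):
        rng = np.random.default_rng(seed)
        pred = rng.integers(0, 3, (16, 16))
        gt = rng.integers(0, 3, (16, 16))
        ignore = rng.random((16, 16)) < 0.2
        for c in range(3):
            a = confusion_areas(pred, gt, ignore, c)
            assert (a.tp, a.fp, a.fn) == tally_oracle(pred, gt, ignore, c)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_areas(np.zeros((4, 4)), np.zeros((4, 5)), None, 0)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            ConfusionAreas(-1, 0, 0)


class TestDiceIoU:
    def test_worked_example(self):
        c = ConfusionAreas(tp=50, fp=10, fn=10)
        assert dice(c) == pytest.approx(100 / 120)
        assert iou(c) == pytest.approx(50 / 70)

    def test_extremes(self):
        assert dice(ConfusionAreas(5, 0, 0)) == 1.0
        assert iou(ConfusionAreas(5, 0, 0)) == 1.0
        assert dice(ConfusionAreas(0, 3, 4)) == 0.0
        assert iou(ConfusionAreas(0, 3, 4)) == 0.0

    def test_all_zero_areas_undefined(self):
        assert math.isnan(dice(ConfusionAreas(0, 0, 0)))
        assert math.isnan(iou(ConfusionAreas(0, 0, 0)))

    @pytest.mark.parametrize("seed", range(10))
    def test_identity_iou_equals_dice_over_two_minus_dice(self, seed):
        rng = np.random.default_rng(seed)
        c = ConfusionAreas(*(int(v) for v in rng.integers(0, 500, 3) + 1))
        d = dice(c)
        assert iou(c) == pytest.approx(d / (2 - d), abs=1e-12)
        assert iou(c) <= d


# ---------------------------------------------------------------------------
# Hausdorff
# ---------------------------------------------------------------------------

class TestHausdorff:
    def test_identity_is_zero(self, rng):
        a = rng.integers(0, 30, (12, 2))
        assert hausdorff(a, a) == 0.0

    def test_three_four_five(self):
        assert directed_hausdorff([(0, 0)], [(3, 4)]) == pytest.approx(5.0)
        assert hausdorff([(0, 0)], [(3, 4)]) == pytest.approx(5.0)

    def test_directed_asymmetry(self):
        a, b = [(0, 0)], [(0, 0), (0, 10)]
        assert directed_hausdorff(a, b) == 0.0
        assert directed_hausdorff(b, a) == 10.0
        assert hausdorff(a, b) == 10.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = [tuple(p) for p in rng.integers(0, 50, (20, 2))]
        b = [tuple(p) for p in rng.integers(0, 50, (20, 2))]
        h = hausdorff(np.array(a), np.array(b))
        assert h == pytest.approx(hausdorff_oracle(a, b), abs=1e-12)
        assert h == pytest.approx(hausdorff(np.array(b), np.array(a)))

    def test_empty_set_undefined(self):
        assert math.isnan(directed_hausdorff(np.empty((0, 2)), [(1, 1)]))
        assert math.isnan(hausdorff([(1, 1)], np.empty((0, 2))))


# ---------------------------------------------------------------------------
# Dataset-level report
# ---------------------------------------------------------------------------

def _confusion_matrix_maps(m):
    """Build flat pred/gt maps realising integer confusion matrix m."""
    gt, pred = [], []
    for g in range(3):
        for p in range(3):
            gt += [g] * m[g][p]
            pred += [p] * m[g][p]
    n = len(gt)
    return np.array(pred).reshape(1, n), np.array(gt).reshape(1, n)


class TestEvaluateDataset:
    def test_perfect_predictions(self, rng):
        maps = [rng.integers(0, 3, (32, 32)) for _ in range(3)]
        report = evaluate_dataset(maps, maps)
        for cname in ("stroma", "benign", "cancer"):
            assert report.per_class[cname]["dice"] == 1.0
            assert report.per_class[cname]["iou"] == 1.0
            assert report.per_class[cname]["hausdorff"] == 0.0
        assert report.average["dice"] == 1.0

    def test_average_is_arithmetic_mean_of_classes(self):
        # confusion matrix chosen so class Dice = (0.9, 0.8, 0.7)
        m = [[9, 0, 1], [0, 8, 2], [1, 2, 7]]
        pred, gt = _confusion_matrix_maps(m)
        report = evaluate_dataset([pred], [gt])
        assert report.per_class["stroma"]["dice"] == pytest.approx(0.9)
        assert report.per_class["benign"]["dice"] == pytest.approx(0.8)
        assert report.per_class["cancer"]["dice"] == pytest.approx(0.7)
        assert report.average["dice"] == pytest.approx(0.8)

    def test_three_image_set_matches_from_scratch_oracle(self):
        rng = np.random.default_rng(3)
        preds = [rng.integers(0, 3, (20, 20)) for _ in range(3)]
        gts = [rng.integers(0, 3, (20, 20)) for _ in range(3)]
        igns = [rng.random((20, 20)) < 0.1 for _ in range(3)]
        report = evaluate_dataset(preds, gts, igns)
        for ci, cname in enumerate(("stroma", "benign", "cancer")):
            tp = fp = fn = 0
            hds = []
            for p, g, m in zip(preds, gts, igns):
                t = tally_oracle(p, g, m, ci)
                tp, fp, fn = tp + t[0], fp + t[1], fn + t[2]
                a = [tuple(q) for q in points_of_class(g, ci, m)]
                b = [tuple(q) for q in points_of_class(p, ci, m)]
                if a and b:
                    hds.append(hausdorff_oracle(a, b))
            assert report.per_class[cname]["dice"] == pytest.approx(
                2 * tp / (2 * tp + fp + fn))
            assert report.per_class[cname]["iou"] == pytest.approx(
                tp / (tp + fp + fn))
            assert report.per_class[cname]["hausdorff"] == pytest.approx(
                sum(hds) / len(hds))

    def test_micro_dice_invariant_to_image_partition(self, rng):
        pred = rng.integers(0, 3, (8, 64))
        gt = rng.integers(0, 3, (8, 64))
        whole = evaluate_dataset([pred], [gt])
        split = evaluate_dataset(list(pred[:, None, :]), list(gt[:, None, :]))
        for cname in ("stroma", "benign", "cancer"):
            assert whole.per_class[cname]["dice"] == pytest.approx(
                split.per_class[cname]["dice"])

    def test_hausdorff_undefined_policy(self):
        gt = np.zeros((4, 4), int)        # only stroma present
        pred = np.zeros((4, 4), int)
        pred[0, 0] = 2                     # spurious cancer pixel
        report = evaluate_dataset([pred], [gt])
        # cancer present in exactly one map -> flagged, mean undefined
        assert report.hausdorff_undefined_images["cancer"] == 1
        assert math.isnan(report.per_class["cancer"]["hausdorff"])
        # benign absent from both -> skipped, not flagged
        assert report.hausdorff_undefined_images["benign"] == 0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_dataset([], [])

    def test_report_table_shape(self, rng):
        maps = [rng.integers(0, 3, (16, 16))]
        frame = evaluate_dataset(maps, maps).to_frame()
        assert list(frame.index) == ["stroma", "benign", "cancer", "average"]
        assert list(frame.columns) == ["dice", "iou", "hausdorff"]
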