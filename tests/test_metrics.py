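"""Evaluation metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from fetalbrain.metrics import (
    c_index, dice, evaluate_regression, evaluate_segmentation, hd95, jaccard,
    rmse, sensitivity_specificity, surface_voxels,
)

# ---------------------------------------------------------------- oracles


def brute_dice(x, y):
    x, y = x.astype(bool), y.astype(bool)
    nx, ny = x.sum(), y.sum()
    if nx == 0 and ny == 0:
        return 1.0
    if nx == 0 or ny == 0:
        return 0.0
    return 2 * (x & y).sum() / (nx + ny)


def brute_hd95(x, y, spacing=(1, 1, 1)):
    ax = surface_voxels(x) * np.asarray(spacing)
    ay = surface_voxels(y) * np.asarray(spacing)
    d = cdist(ax, ay)  # full distance matrix
    return 0.5 * (np.percentile(d.min(axis=1), 95) + np.percentile(d.min(axis=0), 95))


def brute_confusion(x, y):
    tp = fp = tn = fn = 0
    for a, b in zip(x.ravel(), y.ravel()):
        if a and b:
            tp += 1
        elif a and not b:
            fn += 1
        elif not a and b:
            fp += 1
        else:
            tn += 1
    return tp, fp, tn, fn


def brute_cindex(gt, pred):
    num = den = 0.0
    for i in range(len(gt)):
        for j in range(i + 1, len(gt)):
            if gt[i] == gt[j]:
                continue
            den += 1
            if pred[i] == pred[j]:
                num += 0.5
            elif (gt[i] - gt[j]) * (pred[i] - pred[j]) > 0:
                num += 1
    return num / den


class TestDice:
    def test_identical_nonempty_masks(self, rng):
        m = rng.uniform(size=(6, 6, 6)) > 0.5
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = True
        b[3, 3, 3] = True
        assert dice(a, b) == 0.0

    def test_half_overlap_hand_value(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0, 0, 0] = a[0, 0, 1] = True
        b[0, 0, 1] = b[0, 0, 2] = True
        assert dice(a, b) == pytest.approx(0.5)

    def test_empty_conventions(self):
        e = np.zeros((3, 3, 3), bool)
        m = e.copy()
        m[1, 1, 1] = True
        assert dice(e, e) == 1.0
        assert dice(e, m) == 0.0 and dice(m, e) == 0.0

    def test_symmetry_and_jaccard_ordering(self, rng):
        a = rng.uniform(size=(5, 5, 5)) > 0.6
        b = rng.uniform(size=(5, 5, 5)) > 0.6
        assert dice(a, b) == dice(b, a)
        assert jaccard(a, b) <= dice(a, b) + 1e-12


class TestHd95:
    def test_identical_masks_zero(self, rng):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        assert hd95(m, m) == 0.0

    def test_two_single_voxels_three_apart(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 2] = True
        b[5, 2, 2] = True
        assert hd95(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[2, 2, 2] = True
        b[5, 2, 2] = True
        assert hd95(a, b, (2.0, 1.0, 1.0)) == pytest.approx(6.0)

    def test_empty_mask_flagged_undefined(self):
        m = np.zeros((4, 4, 4), bool)
        full = ~m
        assert hd95(m, full) is None

    def test_matches_all_pairs_oracle_on_random_masks(self, rng):
        for _ in range(20):
            a = rng.uniform(size=(8, 8, 8)) > 0.5
            b = rng.uniform(size=(8, 8, 8)) > 0.5
            assert hd95(a, b) == pytest.approx(brute_hd95(a, b), abs=1e-9)


class TestSensitivitySpecificity:
    def test_perfect_prediction(self, rng):
        m = rng.uniform(size=(5, 5, 5)) > 0.5
        assert sensitivity_specificity(m, m) == (1.0, 1.0)

    def test_all_positive_prediction_on_half_positive_truth(self):
        truth = np.zeros((4, 4, 4), bool)
        truth[:2] = True
        pred = np.ones((4, 4, 4), bool)
        assert sensitivity_specificity(truth, pred) == (1.0, 0.0)

    def test_counts_match_exhaustive_enumeration(self, rng):
        truth = rng.uniform(size=(4, 4)) > 0.4
        pred = rng.uniform(size=(4, 4)) > 0.6
        tp, fp, tn, fn = brute_confusion(truth, pred)
        tpr, tnr = sensitivity_specificity(truth, pred)
        assert tpr == pytest.approx(tp / (tp + fn))
        assert tnr == pytest.approx(tn / (tn + fp))

    def test_empty_denominator_flagged(self):
        empty = np.zeros((3, 3, 3), bool)
        tpr, tnr = sensitivity_specificity(empty, empty)
        assert tpr is None and tnr == 1.0


class TestRmse:
    def test_exact_prediction_is_zero(self):
        assert rmse([20, 25, 30], [20, 25, 30]) == 0.0

    def test_plus_minus_one(self):
        assert rmse([1, -1], [0, 0]) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        assert rmse([21, 25, 30], [20, 26, 33]) == pytest.approx(np.sqrt(11 / 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1, 2, 3])


class TestCIndex:
    def test_monotone_prediction_is_one(self):
        assert c_index([1, 2, 3, 4], [10, 20, 30, 40]) == 1.0

    def test_reversed_prediction_is_zero(self):
        assert c_index([1, 2, 3, 4], [4, 3, 2, 1]) == 0.0

    def test_tie_counts_half(self):
        assert c_index([1, 2, 3], [2, 2, 3]) == pytest.approx(5 / 6)

    def test_constant_truth_flagged(self):
        assert c_index([2, 2, 2], [1, 2, 3]) is None

    def test_matches_pair_enumeration_and_lifelines(self, rng):
        from lifelines.utils import concordance_index

        for _ in range(10):
            gt = rng.integers(0, 6, size=12).astype(float)
            pred = rng.normal(size=12)
            ours = c_index(gt, pred)
            assert ours == pytest.approx(brute_cindex(gt, pred), abs=1e-12)
            assert ours == pytest.approx(concordance_index(gt, pred), abs=1e-12)


class TestReports:
    def test_multiclass_report_excludes_undefined_hd95(self, phantom48):
        _, lab, _ = phantom48
        pred = lab.labels.copy()
        pred[pred == 7] = 3  # remove one class entirely from the prediction
        rep = evaluate_segmentation(lab.labels, pred)
        assert rep.per_class[7]["hd95"] is None
        assert rep.n_undefined_hd95 == 1
        assert rep.per_class[1]["dsc"] == 1.0
        assert 0.0 <= rep.macro["dsc"] <= 1.0

    def test_perfect_segmentation_report(self, phantom48):
        _, lab, _ = phantom48
        rep = evaluate_segmentation(lab.labels, lab.labels)
        assert rep.macro["dsc"] == 1.0
        assert rep.macro["hd95"] == 0.0

    def test_regression_report(self):
        rep = evaluate_regression([20.0, 25.0, 30.0], [20.0, 25.0, 30.0])
        assert rep.rmse == 0.0 and rep.c_index == 1.0
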