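import numpy as np
import pytest

from dxafemur.contrast import make_ibd
from dxafemur.errors import ShapeMismatchError
from dxafemur.evaluate import (
    bmd_map,
    class_confusion,
    dataset_accuracy,
    evaluate_dataset,
    image_pass,
    kfold_split,
    mean_dice,
    overlap_scores,
    r_squared,
    roi_bmd,
    score_masks,
)
from dxafemur.phantom import BONE
from dxafemur.roi import Rect


def _random_masks(seed, shape=(8, 8)):
    rng = np.random.default_rng(seed)
    return (
        rng.integers(0, 3, shape).astype(np.int8),
        rng.integers(0, 3, shape).astype(np.int8),
    )


class TestConfusion:
    def test_perfect_prediction(self):
        pred, _ = _random_masks(0)
        for c in range(3):
            tp, tn, fp, fn = class_confusion(pred, pred, c)
            assert fp == 0 and fn == 0 and tp + tn == pred.size

    def test_complement_prediction(self):
        _, truth = _random_masks(1)
        pred = np.where(truth == 2, 0, 2).astype(np.int8)
        tp, tn, fp, fn = class_confusion(pred, truth, 2)
        assert tp == 0 and tn == 0

    def test_matches_counting_loop_oracle(self):
        pred, truth = _random_masks(2)
        for c in range(3):
            tp = tn = fp = fn = 0
            for i in range(8):
                for j in range(8):
                    p, t = pred[i, j] == c, truth[i, j] == c
                    tp += p and t
                    tn += (not p) and (not t)
                    fp += p and not t
                    fn += (not p) and t
            assert class_confusion(pred, truth, c) == (tp, tn, fp, fn)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ShapeMismatchError):
            class_confusion(np.zeros((2, 2)), np.zeros((3, 2)), 0)


class TestOverlap:
    def test_identical_masks(self):
        pred, _ = _random_masks(3)
        ji, dice, eps, theta, fpr, fnr = overlap_scores(pred, pred, 1)
        assert (ji, dice, eps, theta, fpr, fnr) == (1.0, 1.0, 100.0, 100.0, 0.0, 0.0)

    def test_half_overlap_set_arithmetic(self):
        # |A| = |B| = 4, |A n B| = 2 -> JI = 1/3, Dice = 1/2
        pred = np.zeros((4, 4), np.int8)
        truth = np.zeros((4, 4), np.int8)
        pred[0, 0:4] = 2
        truth[0, 2:4] = 2
        truth[1, 0:2] = 2
        ji, dice, *_ = overlap_scores(pred, truth, 2)
        assert ji == pytest.approx(1 / 3)
        assert dice == pytest.approx(1 / 2)

    def test_disjoint_nonempty_sets(self):
        pred = np.zeros((4, 4), np.int8)
        truth = np.zeros((4, 4), np.int8)
        pred[0, 0] = 2
        truth[3, 3] = 2
        ji, dice, *_ = overlap_scores(pred, truth, 2)
        assert ji == 0.0 and dice == 0.0

    def test_absent_from_both_scores_one(self):
        pred = np.zeros((4, 4), np.int8)
        ji, dice, *_ = overlap_scores(pred, pred, 2)
        assert ji == 1.0 and dice == 1.0

    def test_printed_variant_bounded_by_half(self):
        pred, truth = _random_masks(4)
        for c in range(3):
            ji_printed = overlap_scores(pred, truth, c, ji_variant="printed")[0]
            assert ji_printed <= 0.5

    def test_dice_jaccard_identity_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            pred = rng.integers(0, 3, (6, 6)).astype(np.int8)
            truth = rng.integers(0, 3, (6, 6)).astype(np.int8)
            c = int(rng.integers(0, 3))
            ji, dice, *_ = overlap_scores(pred, truth, c)
            assert dice == pytest.approx(2 * ji / (1 + ji))

    def test_symmetric_in_pred_and_truth(self):
        pred, truth = _random_masks(6)
        for c in range(3):
            a = overlap_scores(pred, truth, c)
            b = overlap_scores(truth, pred, c)
            assert a[0] == b[0] and a[1] == b[1]  # JI, Dice symmetric


class TestMeanDice:
    def test_identity(self):
        pred, _ = _random_masks(7)
        assert mean_dice(pred, pred) == 1.0

    def test_composes_from_per_class_scores(self, clean_phantom):
        from dxafemur.contrast import make_ci, normalize_to_8bit
        from dxafemur.segment import baseline_segment

        scan, truth = clean_phantom
        pred = baseline_segment(normalize_to_8bit(make_ci(scan)))
        per_class = [overlap_scores(pred, truth.labels, c)[1] for c in range(3)]
        assert mean_dice(pred, truth.labels) == pytest.approx(np.mean(per_class))


class TestGatedAccuracy:
    @pytest.mark.parametrize("scores,expected", [
        ((0.95, 96, 94), 1),
        ((0.90, 96, 94), 0),  # JI gate fails
        ((0.95, 94, 94), 0),  # sensitivity gate fails
        ((0.95, 96, 92), 0),  # specificity gate fails
        ((0.92, 95, 93), 1),  # boundary is inclusive
    ])
    def test_image_pass_gates(self, scores, expected):
        assert image_pass(*scores) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            image_pass(1.5, 96, 94)
        with pytest.raises(ValueError):
            image_pass(0.95, 101, 94)

    def test_dataset_accuracy_hand_case(self):
        scores = [(0.95, 96, 94), (0.90, 96, 94), (0.95, 94, 94), (0.95, 96, 92)]
        assert dataset_accuracy(scores) == 25.0

    def test_all_passing_and_single_failure(self):
        assert dataset_accuracy([(0.95, 96, 94)] * 3) == 100.0
        assert dataset_accuracy([(0.5, 96, 94)]) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dataset_accuracy([])


class TestKFold:
    def test_ten_by_five_partition(self):
        folds = kfold_split(10, 5, seed=0)
        tests = [set(t) for _, t in folds]
        assert all(len(t) == 2 for t in tests)
        assert set().union(*tests) == set(range(10))
        for i in range(5):
            for j in range(i + 1, 5):
                assert not tests[i] & tests[j]

    def test_train_is_complement(self):
        for train, test in kfold_split(10, 5, seed=0):
            assert sorted(set(train) | set(test)) == list(range(10))
            assert not set(train) & set(test)

    def test_eleven_by_five_sizes(self):
        sizes = sorted(len(t) for _, t in kfold_split(11, 5, seed=1))
        assert sizes == [2, 2, 2, 2, 3]

    def test_reproducible(self):
        a = kfold_split(20, 5, seed=9)
        b = kfold_split(20, 5, seed=9)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tra, trb) and np.array_equal(tea, teb)

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5)


class TestBmd:
    def test_bmd_map_aliases_bone_density_image(self, clean_phantom):
        scan, _ = clean_phantom
        assert np.array_equal(bmd_map(scan), make_ibd(scan).pixels)

    def test_constant_bmd_recovered_per_roi(self, clean_phantom):
        _, truth = clean_phantom
        bmd = np.ones(truth.labels.shape)
        res = roi_bmd(bmd, truth.labels, truth.rois)
        for name, v in res.values.items():
            assert v == pytest.approx(1.0)

    def test_air_roi_reported_absent(self, clean_phantom):
        _, truth = clean_phantom
        res = roi_bmd(np.ones(truth.labels.shape), truth.labels,
                      {"corner": Rect(0, 5, 0, 5)})
        assert res.counts["corner"] == 0
        assert "corner" not in res.values

    def test_matches_direct_masked_means(self, clean_phantom):
        scan, truth = clean_phantom
        bmd = bmd_map(scan)
        res = roi_bmd(bmd, truth.labels, truth.rois)
        for name, rect in truth.rois.items():
            sel = rect.extract(truth.labels) == BONE
            if sel.any():
                assert res.values[name] == pytest.approx(
                    rect.extract(bmd)[sel].mean()
                )

    def test_recovers_true_bmd_ordering(self, clean_dataset):
        # noise-free pixel BMD is affine in true density, so ROI values
        # correlate near-perfectly with the ground truth
        xs, ys = [], []
        for scan, truth in clean_dataset:
            res = roi_bmd(bmd_map(scan), truth.labels, truth.rois)
            for name, v in res.values.items():
                xs.append(truth.true_bmd[name])
                ys.append(v)
        assert r_squared(xs, ys) > 0.999


class TestRSquared:
    def test_perfect_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert r_squared(x, [2 * v + 3 for v in x]) == pytest.approx(1.0)

    def test_sign_ignored(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert r_squared(x, [-v for v in x]) == pytest.approx(1.0)

    def test_matches_definitional_sums(self):
        x = [1.0, 2.0, 4.0, 5.0, 7.0]
        y = [2.0, 3.0, 5.0, 4.0, 8.0]
        n = 5
        sx, sy = sum(x), sum(y)
        sxy = sum(a * b for a, b in zip(x, y))
        sxx = sum(a * a for a in x)
        syy = sum(b * b for b in y)
        r = (n * sxy - sx * sy) / (
            ((n * sxx - sx**2) ** 0.5) * ((n * syy - sy**2) ** 0.5)
        )
        assert r_squared(x, y) == pytest.approx(r * r)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0], [2.0])
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0, 3.0], [1.0, 2.0])


class TestDatasetEvaluation:
    def test_perfect_predictions(self, clean_dataset):
        truths = [t.labels for _, t in clean_dataset]
        summary = evaluate_dataset(truths, truths)
        assert summary.accuracy_pct == 100.0
        assert summary.mean_disc_pct == pytest.approx(100.0)
        assert summary.pixel_accuracy_pct == pytest.approx(100.0)

    def test_scorecard_internal_consistency(self, clean_phantom):
        from dxafemur.contrast import make_ci, normalize_to_8bit
        from dxafemur.segment import baseline_segment

        scan, truth = clean_phantom
        pred = baseline_segment(normalize_to_8bit(make_ci(scan)))
        card = score_masks(pred, truth.labels)
        n = truth.labels.size
        for c in range(3):
            assert sum(card.confusion[c]) == n
            assert card.dice[c] == pytest.approx(
                2 * card.ji[c] / (1 + card.ji[c])
            )
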