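"""Partial-annotation metrics: Dice, masked ROC/AUC, bootstrap bands."""

import numpy as np
import pytest

from camstitch.evaluation import (
    DICE_THRESHOLDS,
    EvaluationError,
    bootstrap_roc,
    dice,
    dice_sweep_arrays,
    dice_threshold_sweep,
    masked_roc_auc,
    patch_metrics,
)
from camstitch.labels import ASPECIFIC, LABEL_TO_INDEX, UNLABELED
from camstitch.synth import LabelMask


def rank_statistic_auc(scores, truth):
    """Independent AUC oracle: P(pos > neg) with ties counted 1/2."""
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestDice:
    def test_perfect_overlap(self):
        m = np.ones((4, 4), bool)
        assert dice(m, m, m) == 1.0

    def test_disjoint_sets(self):
        p = np.zeros((4, 4), bool); p[0] = True
        t = np.zeros((4, 4), bool); t[2] = True
        assert dice(p, t, np.ones((4, 4), bool)) == 0.0

    def test_formula_by_hand(self):
        # |P| = 4, |T| = 6, |P ∩ T| = 3 -> 2*3/10 = 0.6
        p = np.zeros(12, bool); p[:4] = True
        t = np.zeros(12, bool); t[1:7] = True
        assert dice(p, t, np.ones(12, bool)) == pytest.approx(0.6)

    def test_both_empty_in_region_is_one(self):
        z = np.zeros((3, 3), bool)
        assert dice(z, z, np.ones((3, 3), bool)) == 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            dice(np.zeros((2, 2), bool), np.zeros((3, 3), bool),
                 np.zeros((3, 3), bool))

    def test_region_masks_out_pixels(self):
        p = np.array([1, 1, 0, 0], bool)
        t = np.array([1, 0, 0, 1], bool)
        region = np.array([1, 1, 0, 0], bool)  # last pixels invisible
        assert dice(p, t, region) == pytest.approx(2 * 1 / (2 + 1))


class TestDiceSweep:
    def test_grid_is_002_spaced(self):
        assert len(DICE_THRESHOLDS) == 51
        assert np.allclose(np.diff(DICE_THRESHOLDS), 0.02)

    def test_exhaustive_sweep_by_hand(self):
        scores = np.array([0.9, 0.6, 0.4, 0.1])
        truth = np.array([1, 1, 0, 0], bool)
        sweep = dice_sweep_arrays(scores, truth, np.ones(4, bool))
        assert sweep.best_dice == 1.0
        assert sweep.best_threshold == pytest.approx(0.40)  # first achieving it

    def test_all_positive_all_high(self):
        sweep = dice_sweep_arrays(np.ones(5), np.ones(5, bool), np.ones(5, bool))
        assert sweep.best_dice == 1.0

    def test_uninformative_scores_closed_form(self):
        # constant 0.5 scores, half the region positive: at t < 0.5 every
        # pixel is predicted -> Dice = 2|T| / (|region| + |T|) = 2/3
        n = 10
        truth = np.zeros(n, bool); truth[: n // 2] = True
        sweep = dice_sweep_arrays(np.full(n, 0.5), truth, np.ones(n, bool))
        assert sweep.dice_at[0] == pytest.approx(2 / 3)

    def test_tie_broken_toward_lowest_threshold(self):
        scores = np.array([1.0, 1.0, 0.0])
        truth = np.array([1, 1, 0], bool)
        sweep = dice_sweep_arrays(scores, truth, np.ones(3, bool))
        assert sweep.best_dice == 1.0
        assert sweep.best_threshold == 0.0

    def test_label_mask_entry_point(self, rng):
        labels = np.full((20, 20), LABEL_TO_INDEX[UNLABELED], np.uint8)
        labels[:10] = LABEL_TO_INDEX[ASPECIFIC]
        labels[10:15] = LABEL_TO_INDEX["ring"]
        mask = LabelMask(labels)
        scores = rng.random((20, 20))
        sweep = dice_threshold_sweep(scores, mask)
        assert 0.0 <= sweep.best_dice <= 1.0

    def test_empty_region_rejected(self):
        with pytest.raises(EvaluationError):
            dice_sweep_arrays(np.ones(3), np.ones(3, bool), np.zeros(3, bool))


class TestMaskedRoc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truth = np.array([1, 1, 0, 0], bool)
        assert masked_roc_auc(scores, truth).auc == 1.0

    def test_pairwise_example(self):
        # pos {0.9, 0.3}, neg {0.6, 0.2}: 3 of 4 concordant pairs
        scores = np.array([0.9, 0.3, 0.6, 0.2])
        truth = np.array([1, 1, 0, 0], bool)
        assert masked_roc_auc(scores, truth).auc == pytest.approx(0.75)

    def test_single_class_yields_undefined_marker(self):
        r = masked_roc_auc(np.array([0.1, 0.9]), np.array([1, 1], bool))
        assert not r.defined
        assert r.auc is None

    def test_trapezoid_equals_rank_statistic(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = rng.choice(np.linspace(0, 1, 11), size=n)  # many ties
            truth = rng.random(n) < 0.5
            if truth.all() or not truth.any():
                continue
            got = masked_roc_auc(scores, truth).auc
            assert got == pytest.approx(rank_statistic_auc(scores, truth))

    def test_invariant_to_monotone_transform(self, rng):
        scores = rng.random(50)
        truth = rng.random(50) < 0.4
        a = masked_roc_auc(scores, truth).auc
        b = masked_roc_auc(np.exp(3 * scores) - 1, truth).auc
        assert a == pytest.approx(b)

    def test_unlabeled_pixels_never_influence_metrics(self, rng):
        scores = rng.random(100)
        truth = rng.random(100) < 0.5
        region = rng.random(100) < 0.6
        base_auc = masked_roc_auc(scores, truth, region).auc
        base_sweep = dice_sweep_arrays(scores, truth, region)
        flipped = scores.copy()
        flipped[~region] = 1.0 - flipped[~region]
        assert masked_roc_auc(flipped, truth, region).auc == base_auc
        sweep = dice_sweep_arrays(flipped, truth, region)
        assert np.array_equal(sweep.dice_at, base_sweep.dice_at)

    def test_roc_curve_is_monotone(self, rng):
        scores = rng.random(200)
        truth = rng.random(200) < 0.3
        r = masked_roc_auc(scores, truth)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)
        assert r.fpr[0] == 0.0 and r.fpr[-1] == 1.0


def _make_mosaic_pair(rng, n=400, auc_signal=2.0):
    labels = np.full(n, LABEL_TO_INDEX[UNLABELED], np.uint8)
    labeled = rng.random(n) < 0.5
    pos = labeled & (rng.random(n) < 0.4)
    labels[labeled] = LABEL_TO_INDEX["ring"]
    labels[pos] = LABEL_TO_INDEX[ASPECIFIC]
    scores = np.clip(
        rng.normal(0.3, 0.15, n) + (labels == LABEL_TO_INDEX[ASPECIFIC])
        * auc_signal * 0.15,
        0, 1,
    )
    side = int(np.sqrt(n))
    return scores[: side * side].reshape(side, side), LabelMask(
        labels[: side * side].reshape(side, side)
    )


class TestBootstrap:
    def test_duplicated_mosaics_collapse_bands(self, rng):
        pair = _make_mosaic_pair(rng)
        boot = bootstrap_roc([pair, pair, pair], n_boot=50, seed=1)
        assert np.allclose(boot.lower_tpr, boot.upper_tpr)
        assert np.allclose(boot.mean_tpr, boot.lower_tpr)

    def test_pooled_auc_falls_inside_replicate_band(self, rng):
        pairs = [_make_mosaic_pair(rng) for _ in range(10)]
        boot = bootstrap_roc(pairs, n_boot=200, seed=1)
        pooled = masked_roc_auc(
            np.concatenate([s[m.labeled_region()] for s, m in pairs]),
            np.concatenate(
                [m.pixels_of(ASPECIFIC)[m.labeled_region()] for _, m in pairs]
            ),
        )
        lo, hi = np.percentile(boot.replicate_aucs, [2.5, 97.5])
        assert lo <= pooled.auc <= hi
        assert np.all(boot.lower_tpr <= boot.mean_tpr + 1e-12)
        assert np.all(boot.mean_tpr <= boot.upper_tpr + 1e-12)

    def test_single_class_everywhere_rejected(self):
        labels = np.full((10, 10), LABEL_TO_INDEX["ring"], np.uint8)
        pair = (np.zeros((10, 10)), LabelMask(labels))
        with pytest.raises(EvaluationError):
            bootstrap_roc([pair, pair], n_boot=5, seed=0)

    def test_replicates_are_seeded(self, rng):
        pairs = [_make_mosaic_pair(rng) for _ in range(4)]
        a = bootstrap_roc(pairs, n_boot=20, seed=3)
        b = bootstrap_roc(pairs, n_boot=20, seed=3)
        assert np.array_equal(a.replicate_aucs, b.replicate_aucs)


class TestPatchMetrics:
    def test_all_correct(self):
        acc, roc = patch_metrics([0.9, 0.8, 0.1], [1, 1, 0])
        assert acc == 1.0
        assert roc.auc == 1.0

    def test_mixed_example_by_enumeration(self):
        # positives {0.6, 0.45}, negatives {0.4, 0.55}: 3 of 4 pairs
        # concordant -> AUC 0.75; at t = 0.5 two patches misclassified
        acc, roc = patch_metrics([0.6, 0.4, 0.55, 0.45], [1, 0, 0, 1])
        assert acc == 0.5
        assert roc.auc == pytest.approx(
            rank_statistic_auc(
                np.array([0.6, 0.4, 0.55, 0.45]), np.array([1, 0, 0, 1], bool)
            )
        )
        assert roc.auc == pytest.approx(0.75)

    def test_single_class_accuracy_only(self):
        acc, roc = patch_metrics([0.9, 0.7], [1, 1])
        assert acc == 1.0
        assert not roc.defined
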