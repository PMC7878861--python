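"""Segmentation and classification metrics under partial annotation.

All pixel-level metrics are computed only over the labeled evaluation
region; the positive class is always aspecific, with the five benign
sub-labels collapsed into one negative class.  Regions containing a
single class yield an explicit undefined ROC result rather than a silent
0 or 1.  Includes the 0.02-step Dice threshold sweep and the
mosaic-resampling bootstrap ROC with percentile confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .labels import ASPECIFIC
from .stitch import SegmentationMap
from .synth import LabelMask

#: The Dice sweep threshold grid: 0, 0.02, ..., 1.00.
DICE_THRESHOLDS: np.ndarray = np.round(np.arange(0, 51) * 0.02, 2)


class EvaluationError(ValueError):
    pass


@dataclass
class RocCurve:
    """ROC points and trapezoidal AUC; ``defined`` is False when the
    evaluation region contains a single class (AUC is then None)."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float | None
    n_pos: int
    n_neg: int
    defined: bool = True

    @classmethod
    def undefined(cls, n_pos: int, n_neg: int) -> "RocCurve":
        return cls(
            fpr=np.empty(0), tpr=np.empty(0), auc=None,
            n_pos=n_pos, n_neg=n_neg, defined=False,
        )


@dataclass
class DiceSweep:
    thresholds: np.ndarray
    dice_at: np.ndarray
    best_threshold: float
    best_dice: float


@dataclass
class BootstrapRoc:
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    lower_tpr: np.ndarray
    upper_tpr: np.ndarray
    replicate_aucs: np.ndarray
    n_boot: int
    resample_size: int
    n_redrawn: int = 0
    meta: dict = field(default_factory=dict)


def dice(
    pred_mask: np.ndarray, truth_mask: np.ndarray, eval_region: np.ndarray
) -> float:
    """Dice coefficient 2|P∩T| / (|P| + |T|) restricted to ``eval_region``.

    Returns 1.0 when both sets are empty within the region.
    """
    pred_mask, truth_mask, eval_region = (
        np.asarray(a, dtype=bool) for a in (pred_mask, truth_mask, eval_region)
    )
    if not (pred_mask.shape == truth_mask.shape == eval_region.shape):
        raise EvaluationError("mask shapes differ")
    p = pred_mask & eval_region
    t = truth_mask & eval_region
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & t).sum()) / denom


def _as_scores_truth_region(seg, mask):
    if isinstance(seg, SegmentationMap):
        seg = seg.scores
    if isinstance(mask, LabelMask):
        truth = mask.pixels_of(ASPECIFIC)
        region = mask.labeled_region()
    else:
        raise EvaluationError("mask must be a LabelMask (or use the array API)")
    return np.asarray(seg), truth, region


def dice_sweep_arrays(
    scores: np.ndarray, truth: np.ndarray, eval_region: np.ndarray
) -> DiceSweep:
    """Dice at every threshold on the 0.02 grid (rule: score > t); ties in
    the maximum break toward the lowest threshold."""
    eval_region = np.asarray(eval_region, dtype=bool)
    if not eval_region.any():
        raise EvaluationError("evaluation region is empty")
    s = np.asarray(scores)[eval_region].ravel()
    t = np.asarray(truth, dtype=bool)[eval_region].ravel()
    n_t = int(t.sum())
    dice_at = np.empty(len(DICE_THRESHOLDS))
    for i, thr in enumerate(DICE_THRESHOLDS):
        p = s > thr
        denom = int(p.sum()) + n_t
        dice_at[i] = 1.0 if denom == 0 else 2.0 * int((p & t).sum()) / denom
    best = int(np.argmax(dice_at))  # first occurrence = lowest threshold
    return DiceSweep(
        thresholds=DICE_THRESHOLDS.copy(), dice_at=dice_at,
        best_threshold=float(DICE_THRESHOLDS[best]), best_dice=float(dice_at[best]),
    )


def dice_threshold_sweep(
    seg: SegmentationMap | np.ndarray, mask: LabelMask
) -> DiceSweep:
    """Dice sweep of an aspecific score map against a partial annotation."""
    scores, truth, region = _as_scores_truth_region(seg, mask)
    return dice_sweep_arrays(scores, truth, region)


def masked_roc_auc(
    scores: np.ndarray,
    truth: np.ndarray,
    eval_region: np.ndarray | None = None,
) -> RocCurve:
    """ROC over labeled pixels only; trapezoidal AUC.

    The AUC equals the rank statistic P(random positive outscores a random
    negative, ties 1/2).  A single-class region returns the explicit
    undefined marker.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if eval_region is not None:
        region = np.asarray(eval_region, dtype=bool).ravel()
        if region.shape != scores.shape:
            raise EvaluationError("evaluation region shape differs from scores")
        scores, truth = scores[region], truth[region]
    n_pos, n_neg = int(truth.sum()), int((~truth).sum())
    if n_pos == 0 or n_neg == 0:
        return RocCurve.undefined(n_pos, n_neg)
    fpr, tpr, _ = _sk_roc_curve(truth.astype(int), scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


def masked_roc_of(seg: SegmentationMap | np.ndarray, mask: LabelMask) -> RocCurve:
    scores, truth, region = _as_scores_truth_region(seg, mask)
    return masked_roc_auc(scores, truth, region)


def _interp_tpr(curve: RocCurve, fpr_grid: np.ndarray) -> np.ndarray:
    tpr = np.interp(fpr_grid, curve.fpr, curve.tpr)
    tpr[0], tpr[-1] = 0.0, 1.0
    return tpr


def bootstrap_roc(
    per_mosaic: list[tuple[SegmentationMap | np.ndarray, LabelMask]],
    n_boot: int = 1000,
    seed: int = 0,
    resample_size: int | None = None,
    n_grid: int = 101,
    max_redraws: int = 10_000,
) -> BootstrapRoc:
    """Mosaic-resampling bootstrap of the pooled-pixel ROC.

    Each replicate draws ``resample_size`` mosaics with replacement
    (default: the number of test mosaics), pools their labeled pixels,
    and computes one ROC; true-positive rates are linearly interpolated
    onto a common false-positive-rate grid, and the mean plus 2.5/97.5
    percentile bands are returned.  Replicates whose pooled pixels contain
    a single class are redrawn (count reported).
    """
    if len(per_mosaic) < 2:
        raise EvaluationError("bootstrap needs at least two mosaics")
    pooled = [_as_scores_truth_region(s, m) for s, m in per_mosaic]
    flat = [
        (sc[reg].ravel(), tr[reg].ravel()) for sc, tr, reg in pooled
    ]
    if all((t.sum() == 0) or (t.sum() == t.size) for _, t in flat):
        # no single mosaic is two-class; pooling may still work unless all
        # mosaics share one class
        labels = np.concatenate([t for _, t in flat])
        if labels.all() or not labels.any():
            raise EvaluationError("all mosaics carry a single class")
    m = len(flat)
    size = resample_size if resample_size is not None else m
    rng = np.random.default_rng(seed)
    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    tprs = np.empty((n_boot, n_grid))
    aucs = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for _attempt in range(max_redraws):
            idx = rng.integers(0, m, size=size)
            s = np.concatenate([flat[i][0] for i in idx])
            t = np.concatenate([flat[i][1] for i in idx])
            curve = masked_roc_auc(s, t)
            if curve.defined:
                break
            redrawn += 1
        else:
            raise EvaluationError("could not draw a two-class replicate")
        tprs[b] = _interp_tpr(curve, fpr_grid)
        aucs[b] = curve.auc
    return BootstrapRoc(
        fpr_grid=fpr_grid,
        mean_tpr=tprs.mean(axis=0),
        lower_tpr=np.percentile(tprs, 2.5, axis=0),
        upper_tpr=np.percentile(tprs, 97.5, axis=0),
        replicate_aucs=aucs,
        n_boot=n_boot,
        resample_size=size,
        n_redrawn=redrawn,
    )


def patch_metrics(
    scores, labels, threshold: float = 0.5
) -> tuple[float, RocCurve]:
    """Accuracy at a fixed score threshold plus the full ROC/AUC.

    ``labels`` are 1/True for aspecific.  With a single class present the
    accuracy is still computed and the ROC carries the undefined marker.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.size == 0:
        raise EvaluationError("empty score list")
    acc = float(np.mean((scores > threshold) == labels))
    return acc, masked_roc_auc(scores, labels)
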