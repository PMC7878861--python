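"""Weak-label patch dataset construction from partially annotated mosaics.

Pixel-annotated mosaics become a class-balanced, weakly labeled patch
dataset in four steps: a patient-wise 70/10/20 split that tries to
preserve per-class pixel ratios, x4 anti-aliased downsampling, quota-based
extraction of square patches labeled by their center pixel, and
training-time augmentation (random crop, flips, grayscale jitter, noise,
blur).  The pixel labels are used only to pick patch centers and later to
evaluate; training sees a single weak label per patch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .labels import ASPECIFIC, FINE_LABELS, weak_label_of
from .synth import LabelMask, Mosaic

SPLITS = ("train", "val", "test")


class DatasetError(ValueError):
    pass


@dataclass
class SplitAssignment:
    """Patient -> split mapping with realized per-split patient counts."""

    assignment: dict[str, str]

    def split_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]

    def patients_in(self, split: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == split]

    @property
    def counts(self) -> dict[str, int]:
        return {s: len(self.patients_in(s)) for s in SPLITS}


def largest_remainder_counts(n: int, ratios: Sequence[float]) -> list[int]:
    """Apportion ``n`` items to groups by largest-remainder rounding.

    Ties in the fractional parts are broken toward earlier groups, so
    157 with ratios (0.7, 0.1, 0.2) gives (110, 16, 31).
    """
    exact = np.asarray(ratios, dtype=float) * n
    base = np.floor(exact + 1e-9).astype(int)
    # round so float noise cannot flip a genuine tie (e.g. 12 * 0.7)
    rem = np.round(exact - base, 9)
    short = n - int(base.sum())
    # stable sort descending on remainder -> earlier groups win ties
    order = np.argsort(-rem, kind="stable")
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


def split_patient_counts(
    patient_label_counts: Mapping[str, Mapping[str, int]],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Patient-disjoint split from per-patient label-pixel count vectors.

    Patient counts per split follow largest-remainder rounding of the
    ratios.  Within those capacities, patients are assigned greedily
    (largest patients first) to the split whose running per-class pixel
    composition would deviate least from the global composition, which
    approximately preserves the label ratio of every class in every split.
    """
    if len(ratios) != len(SPLITS):
        raise DatasetError("ratios must have three entries (train, val, test)")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise DatasetError("ratios must be positive and sum to 1")
    patients = list(patient_label_counts)
    if len(patients) < len(SPLITS):
        raise DatasetError("need at least as many patients as splits")

    capacities = dict(zip(SPLITS, largest_remainder_counts(len(patients), ratios)))
    labels = list(FINE_LABELS)
    vecs = {
        p: np.array([patient_label_counts[p].get(l, 0) for l in labels], dtype=float)
        for p in patients
    }
    total = sum(vecs.values())
    total_sum = total.sum()
    global_ratio = total / total_sum if total_sum > 0 else np.zeros(len(labels))

    rng = np.random.default_rng(seed)
    order = sorted(
        rng.permutation(patients).tolist(),
        key=lambda p: -vecs[p].sum(),
    )
    assigned: dict[str, str] = {}
    running = {s: np.zeros(len(labels)) for s in SPLITS}
    placed = {s: 0 for s in SPLITS}
    for p in order:
        best, best_cost = None, None
        for s, r in zip(SPLITS, ratios):
            if placed[s] >= capacities[s]:
                continue
            cand = running[s] + vecs[p]
            tot = cand.sum()
            comp = cand / tot if tot > 0 else cand
            cost = float(np.abs(comp - global_ratio).sum())
            if best_cost is None or cost < best_cost:
                best, best_cost = s, cost
        assert best is not None
        assigned[p] = best
        running[best] += vecs[p]
        placed[best] += 1
    return SplitAssignment(assignment=assigned)


def split_by_patient(
    collection: Iterable[tuple[Mosaic, LabelMask]],
    ratios: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> SplitAssignment:
    """Patient-disjoint train/val/test split of an annotated collection."""
    counts: dict[str, dict[str, int]] = {}
    for mosaic, mask in collection:
        pid = mosaic.patient_id
        if pid in counts:
            raise DatasetError(f"duplicate patient id {pid!r}")
        counts[pid] = {l: int(mask.pixels_of(l).sum()) for l in FINE_LABELS}
    return split_patient_counts(counts, ratios=ratios, seed=seed)


def downsample(raster: np.ndarray, factor: int = 4, kind: str = "intensity") -> np.ndarray:
    """Reduce a raster by an integer factor in each direction.

    Intensity rasters use block-mean (anti-aliased) reduction; label
    rasters use nearest-neighbor (block-center) sampling so categories are
    never mixed.  Output dims are ``floor(input / factor)``; trailing rows
    and columns that do not fill a block are dropped.
    """
    if factor < 1:
        raise DatasetError("downsampling factor must be >= 1")
    raster = np.asarray(raster)
    h, w = raster.shape
    if h < factor or w < factor:
        raise DatasetError("raster smaller than the downsampling factor")
    if factor == 1:
        return raster.copy()
    oh, ow = h // factor, w // factor
    if kind == "intensity":
        blocks = raster[: oh * factor, : ow * factor].reshape(oh, factor, ow, factor)
        return blocks.mean(axis=(1, 3))
    if kind == "label":
        c = factor // 2
        return raster[c :: factor, c :: factor][:oh, :ow].copy()
    raise DatasetError(f"unknown raster kind {kind!r}")


def downsample_pair(
    mosaic: Mosaic, mask: LabelMask, factor: int = 4
) -> tuple[Mosaic, LabelMask]:
    return (
        Mosaic(
            pixels=downsample(mosaic.pixels, factor, "intensity"),
            patient_id=mosaic.patient_id,
            pixel_pitch=mosaic.pixel_pitch * factor,
        ),
        LabelMask(labels=downsample(mask.labels, factor, "label")),
    )


@dataclass
class WeakPatch:
    """A square grayscale window with a single weak (binary) label.

    ``source_label`` (the fine label of the center pixel) is bookkeeping
    only and is never used in training.
    """

    pixels: np.ndarray
    weak_label: str          # "benign" | "aspecific"
    source_label: str        # one of the six fine labels
    mosaic_id: str
    center_xy: tuple[int, int]  # (row, col) of the center pixel


def _valid_centers(mask: LabelMask, label: str, patch_size: int) -> np.ndarray:
    """Flat indices of ``label`` pixels whose window fits inside the mosaic
    (center at least patch_size//2 away from every border)."""
    h, w = mask.shape
    half = patch_size // 2
    lo_r, hi_r = half, h - patch_size + half   # inclusive bounds on center row
    lo_c, hi_c = half, w - patch_size + half
    if hi_r < lo_r or hi_c < lo_c:
        return np.empty(0, dtype=np.intp)
    sel = mask.pixels_of(label)
    valid = np.zeros_like(sel)
    valid[lo_r : hi_r + 1, lo_c : hi_c + 1] = True
    return np.flatnonzero(sel & valid)


def sample_weak_patches(
    mosaic: Mosaic,
    mask: LabelMask,
    quota: Mapping[str, int],
    patch_size: int = 500,
    seed: int = 0,
    with_replacement: bool = True,
) -> list[WeakPatch]:
    """Extract quota-many patches per fine label from one (downsampled)
    mosaic, each centered on a uniformly sampled pixel carrying that label.

    Centers are drawn only from pixels whose full window fits inside the
    mosaic, so the center-pixel labeling rule is exact without padding.  A
    label with quota > 0 but no valid centers in this mosaic yields zero
    patches here (collection-level allocation reassigns it elsewhere).
    """
    if mosaic.shape != mask.shape:
        raise DatasetError("mosaic and mask shapes differ")
    if any(q < 0 for q in quota.values()):
        raise DatasetError("quotas must be non-negative")
    h, w = mask.shape
    rng = np.random.default_rng(seed)
    half = patch_size // 2
    out: list[WeakPatch] = []
    for label in FINE_LABELS:
        q = int(quota.get(label, 0))
        if q == 0:
            continue
        centers = _valid_centers(mask, label, patch_size)
        if centers.size == 0:
            continue
        if with_replacement:
            picks = rng.choice(centers, size=q, replace=True)
        else:
            picks = rng.choice(centers, size=min(q, centers.size), replace=False)
        for flat in picks:
            r, c = int(flat // w), int(flat % w)
            win = mosaic.pixels[r - half : r - half + patch_size,
                                c - half : c - half + patch_size]
            out.append(
                WeakPatch(
                    pixels=win.copy(),
                    weak_label=weak_label_of(label),
                    source_label=label,
                    mosaic_id=mosaic.patient_id,
                    center_xy=(r, c),
                )
            )
    return out


def allocate_quotas(
    masks: Sequence[LabelMask],
    quota: Mapping[str, int],
    patch_size: int = 500,
    strict: bool = True,
) -> list[dict[str, int]]:
    """Distribute a collection-level per-label quota over mosaics in
    proportion to each mosaic's share of that label's (samplable) pixels.

    Largest-remainder rounding keeps the per-label totals exact.  A label
    requested with positive quota but absent from every mosaic raises when
    ``strict``; otherwise it is dropped (useful for very small splits).
    """
    out: list[dict[str, int]] = [dict() for _ in masks]
    for label, q in quota.items():
        q = int(q)
        if q < 0:
            raise DatasetError("quotas must be non-negative")
        if q == 0:
            continue
        counts = np.array(
            [_valid_centers(m, label, patch_size).size for m in masks], dtype=float
        )
        total = counts.sum()
        if total == 0:
            if not strict:
                continue
            raise DatasetError(
                f"label {label!r} has no samplable pixels in the whole collection"
            )
        shares = counts / total
        alloc = largest_remainder_counts(q, shares)
        for i, a in enumerate(alloc):
            if a:
                out[i][label] = a
    return out


def build_patch_dataset(
    collection: Sequence[tuple[Mosaic, LabelMask]],
    quota: Mapping[str, int],
    patch_size: int = 500,
    seed: int = 0,
    strict: bool = True,
) -> list[WeakPatch]:
    """Quota-exact weak-patch dataset over a whole (already downsampled)
    collection; per-mosaic contributions are proportional to label content."""
    per_mosaic = allocate_quotas(
        [m for _, m in collection], quota, patch_size, strict=strict
    )
    rng = np.random.default_rng(seed)
    patches: list[WeakPatch] = []
    for (mosaic, mask), q in zip(collection, per_mosaic):
        if q:
            patches.extend(
                sample_weak_patches(
                    mosaic, mask, q, patch_size=patch_size,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return patches


def default_quota(per_benign_subclass: int = 5000) -> dict[str, int]:
    """Balanced quota: a fixed count per benign subclass and an aspecific
    quota matching the total benign count."""
    q = {l: per_benign_subclass for l in FINE_LABELS if l != ASPECIFIC}
    q[ASPECIFIC] = per_benign_subclass * (len(FINE_LABELS) - 1)
    return q


@dataclass(frozen=True)
class AugmentConfig:
    """Training-time augmentation: crop, flips, grayscale jitter, noise, blur."""

    crop_size: int = 256
    random_crop: bool = True
    hflip: bool = True
    vflip: bool = True
    brightness: float = 0.1      # additive jitter half-range
    contrast: float = 0.1        # multiplicative jitter half-range
    noise_variance: float = 0.002
    blur_sigma_max: float = 1.0

    @classmethod
    def disabled(cls, crop_size: int = 256) -> "AugmentConfig":
        return cls(
            crop_size=crop_size, random_crop=False, hflip=False, vflip=False,
            brightness=0.0, contrast=0.0, noise_variance=0.0, blur_sigma_max=0.0,
        )


def augment_patch(
    patch: WeakPatch | np.ndarray, cfg: AugmentConfig, seed: int = 0
) -> np.ndarray:
    """Return a ``crop_size`` x ``crop_size`` augmented view in [0, 1].

    With every augmentation disabled the result is the deterministic
    center crop of the patch.
    """
    pixels = patch.pixels if isinstance(patch, WeakPatch) else np.asarray(patch)
    h, w = pixels.shape
    cs = cfg.crop_size
    if cs > min(h, w):
        raise DatasetError(f"crop size {cs} exceeds patch size {(h, w)}")
    rng = np.random.default_rng(seed)
    if cfg.random_crop and (h > cs or w > cs):
        r0 = int(rng.integers(0, h - cs + 1))
        c0 = int(rng.integers(0, w - cs + 1))
    else:
        r0, c0 = (h - cs) // 2, (w - cs) // 2
    out = pixels[r0 : r0 + cs, c0 : c0 + cs].astype(np.float64, copy=True)
    if cfg.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        out = out[::-1, :]
    if cfg.contrast > 0:
        gain = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        out = (out - out.mean()) * gain + out.mean()
    if cfg.brightness > 0:
        out = out + rng.uniform(-cfg.brightness, cfg.brightness)
    if cfg.noise_variance > 0:
        out = out + np.sqrt(cfg.noise_variance) * rng.standard_normal(out.shape)
    if cfg.blur_sigma_max > 0:
        sigma = rng.uniform(0.0, cfg.blur_sigma_max)
        if sigma > 1e-3:
            out = ndimage.gaussian_filter(out, sigma, mode="nearest")
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


def patch_manifest_rows(
    patches: Sequence[WeakPatch], splits: SplitAssignment | None = None
) -> list[dict[str, object]]:
    """Manifest rows (mosaic id, center, labels, split) for CSV/JSON export;
    the manifest is authoritative, patches can be re-extracted from it."""
    rows = []
    for p in patches:
        rows.append(
            {
                "mosaic_id": p.mosaic_id,
                "center_row": p.center_xy[0],
                "center_col": p.center_xy[1],
                "source_label": p.source_label,
                "weak_label": p.weak_label,
                "split": splits.split_of(p.mosaic_id) if splits else "",
            }
        )
    return rows
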