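"""End-to-end experiment orchestration: synth -> dataset -> train ->
segment -> evaluate, from a single config with recorded seeds.

``run_experiment`` reproduces the full study design at a configurable
scale: generate annotated mosaics (one patient each), downsample x4,
split patient-wise 70/10/20, build balanced weak-patch sets per split,
train the patch classifier, then sweep stitching configurations — the
cross product of CAM method, step size and Gaussian sigma (plus plain
averaging) — producing one (AUC, best Dice) row per run, the machine
analogue of a step-by-sigma results table.  A mosaic-resampling bootstrap
ROC with 95% bands is computed for the best row per CAM method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from matplotlib import colormaps
import yaml

from .backbone import TrainConfig, TrainResult, train_classifier, save_checkpoint
from .dataset import (
    AugmentConfig,
    SplitAssignment,
    augment_patch,
    build_patch_dataset,
    downsample_pair,
    patch_manifest_rows,
    split_by_patient,
)
from .evaluation import (
    BootstrapRoc,
    DiceSweep,
    RocCurve,
    bootstrap_roc,
    dice_threshold_sweep,
    masked_roc_auc,
    patch_metrics,
)
from .io import save_segmentation, write_manifest_csv
from .labels import ASPECIFIC
from .stitch import SegmentationMap, StitchConfig
from .synth import LabelMask, Mosaic, SyntheticSpec, generate_collection


@dataclass(frozen=True)
class SweepSpec:
    """Cross product of stitching choices to evaluate.

    ``sigmas`` lists Gaussian widths; ``None`` entries denote plain
    (uniform) averaging.  The default grid mirrors the full-scale study:
    3 step sizes x (no-Gaussian + 8 sigma values) per CAM method.
    """

    steps: tuple[int, ...] = (25, 50, 100)
    sigmas: tuple[float | None, ...] = (None, 1.0, 2.5, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0)
    cam_methods: tuple[str, ...] = ("cam", "scorecam")
    window: int = 256

    def configs(self) -> list[StitchConfig]:
        out = []
        for method in self.cam_methods:
            for step in self.steps:
                for sigma in self.sigmas:
                    out.append(
                        StitchConfig(
                            window=self.window, step=step,
                            weighting="uniform" if sigma is None else "gaussian",
                            sigma=(1.0, 1.0) if sigma is None else (sigma, sigma),
                            cam_method=method,
                        )
                    )
        return out


@dataclass
class RunConfig:
    """One experiment: data recipe, training recipe, stitching sweep."""

    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    downsample_factor: int = 4
    split_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    patch_size: int = 500
    quota_per_subclass: dict[str, int] = field(
        default_factory=lambda: {"train": 5000, "val": 700, "test": 1400}
    )
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    sweep: SweepSpec = field(default_factory=SweepSpec)
    n_boot: int = 1000
    seed: int = 0

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "RunConfig":
        """Desk-scale preset: 12 high-contrast mosaics of 512^2 used at
        native scale, 64-pixel crops/windows, short training.

        Downsampling is skipped here so the 64-pixel window keeps a
        representative ratio to the labeled structures; the full-scale
        preset applies the x4 reduction to its much larger mosaics.
        """
        spec = SyntheticSpec(
            mosaic_shape=(512, 512), n_mosaics=12, blob_sigma=48.0
        ).easy()
        return cls(
            spec=spec,
            downsample_factor=1,
            patch_size=72,
            quota_per_subclass={"train": 40, "val": 12, "test": 24},
            augment=AugmentConfig(crop_size=64, blur_sigma_max=0.5,
                                  noise_variance=0.001),
            train=TrainConfig(epochs=20, lr=0.02, dropout=0.25, batch_size=64),
            sweep=SweepSpec(steps=(16, 32, 64), window=64),
            n_boot=200,
            seed=seed,
        )


@dataclass
class SweepRow:
    cam_method: str
    step: int
    sigma: float | None
    auc: float | None
    best_dice: float
    best_threshold: float


@dataclass
class RunResult:
    config: RunConfig
    splits: SplitAssignment
    train_result: TrainResult
    patch_accuracy: float
    patch_roc: RocCurve
    table: list[SweepRow]
    bootstrap: dict[str, BootstrapRoc]
    pooled_roc: dict[str, RocCurve]
    test_collection: list[tuple[Mosaic, LabelMask]]
    best_seg: dict[str, list[SegmentationMap]] = field(default_factory=dict)


def _quota_for(spec_quota: int) -> dict[str, int]:
    from .dataset import default_quota

    return default_quota(spec_quota)


def _patch_arrays(patches, aug_cfg: AugmentConfig, seed: int, train_mode: bool):
    """Stack patches into (N, S, S) crops + binary labels.  Training
    patches get the full augmentation pipeline (one seeded draw each);
    validation/test patches get deterministic center crops."""
    rng = np.random.default_rng(seed)
    cfg = aug_cfg if train_mode else AugmentConfig.disabled(aug_cfg.crop_size)
    X = np.stack(
        [augment_patch(p, cfg, seed=int(rng.integers(0, 2**31 - 1))) for p in patches]
    )
    y = np.array([1.0 if p.weak_label == ASPECIFIC else 0.0 for p in patches])
    return X, y


def run_experiment(
    cfg: RunConfig, workdir: str | Path | None = None
) -> RunResult:
    """Run the whole pipeline; optionally persist artifacts under ``workdir``."""
    rng = np.random.default_rng(cfg.seed)
    seeds = {k: int(rng.integers(0, 2**31 - 1))
             for k in ("synth", "split", "dataset", "train", "boot")}
    wd = Path(workdir) if workdir is not None else None
    if wd is not None:
        wd.mkdir(parents=True, exist_ok=True)

    collection = generate_collection(cfg.spec, seeds["synth"])
    collection = [
        downsample_pair(m, k, cfg.downsample_factor) for m, k in collection
    ]
    splits = split_by_patient(collection, cfg.split_ratios, seed=seeds["split"])
    by_split = {
        s: [c for c in collection if splits.split_of(c[0].patient_id) == s]
        for s in ("train", "val", "test")
    }
    for s, items in by_split.items():
        if not items:
            raise RuntimeError(f"split {s!r} received no mosaics")

    ds_rng = np.random.default_rng(seeds["dataset"])
    patches = {
        s: build_patch_dataset(
            by_split[s], _quota_for(cfg.quota_per_subclass[s]),
            patch_size=cfg.patch_size, seed=int(ds_rng.integers(0, 2**31 - 1)),
            strict=False,  # tiny splits may lack a benign subclass entirely
        )
        for s in ("train", "val", "test")
    }
    arrays = {
        s: _patch_arrays(
            patches[s], cfg.augment, int(ds_rng.integers(0, 2**31 - 1)),
            train_mode=(s == "train"),
        )
        for s in ("train", "val", "test")
    }

    tr = train_classifier(
        *arrays["train"], *arrays["val"], cfg.train, seed=seeds["train"]
    )
    test_X, test_y = arrays["test"]
    test_scores = tr.model.predict_proba(test_X)
    patch_acc, patch_roc = patch_metrics(test_scores, test_y, cfg.train.threshold)

    # Per-window contributions depend only on CAM method and position, so
    # compute them once on the union grid and reuse across the whole sweep.
    from .stitch import accumulate_contributions, compute_contributions, stitch_kernel, window_grid

    win = cfg.sweep.window
    contrib_cache: dict[str, list[dict]] = {}
    union_grids: list[list[tuple[int, int]]] = []
    for mosaic, _ in by_split["test"]:
        grid = sorted(
            {
                pos
                for step in cfg.sweep.steps
                for pos in window_grid(mosaic.shape, win, step)
            }
        )
        union_grids.append(grid)
    for method in cfg.sweep.cam_methods:
        contrib_cache[method] = [
            compute_contributions(tr.model, mosaic.pixels, grid, win, method)
            for (mosaic, _), grid in zip(by_split["test"], union_grids)
        ]

    table: list[SweepRow] = []
    seg_cache: dict[tuple, list[SegmentationMap]] = {}
    for sc in cfg.sweep.configs():
        kernel = stitch_kernel(sc)
        segs = [
            accumulate_contributions(
                mosaic.shape, contribs, window_grid(mosaic.shape, win, sc.step),
                kernel, sc,
            )
            for (mosaic, _), contribs in zip(
                by_split["test"], contrib_cache[sc.cam_method]
            )
        ]
        key = (sc.cam_method, sc.step,
               None if sc.weighting == "uniform" else sc.sigma[0])
        seg_cache[key] = segs
        pooled_scores = np.concatenate(
            [s.scores[k.labeled_region()] for s, (_, k) in zip(segs, by_split["test"])]
        )
        pooled_truth = np.concatenate(
            [k.pixels_of(ASPECIFIC)[k.labeled_region()] for _, k in by_split["test"]]
        )
        roc = masked_roc_auc(pooled_scores, pooled_truth)
        sweeps = [
            dice_threshold_sweep(s, k) for s, (_, k) in zip(segs, by_split["test"])
        ]
        pooled_sweep = _pooled_dice(segs, [k for _, k in by_split["test"]])
        table.append(
            SweepRow(
                cam_method=sc.cam_method, step=sc.step, sigma=key[2],
                auc=roc.auc, best_dice=pooled_sweep.best_dice,
                best_threshold=pooled_sweep.best_threshold,
            )
        )

    boots: dict[str, BootstrapRoc] = {}
    pooled: dict[str, RocCurve] = {}
    best_seg: dict[str, list[SegmentationMap]] = {}
    for method in cfg.sweep.cam_methods:
        rows = [r for r in table if r.cam_method == method and r.auc is not None]
        best = max(rows, key=lambda r: r.auc)
        segs = seg_cache[(best.cam_method, best.step, best.sigma)]
        per_mosaic = list(zip(segs, [k for _, k in by_split["test"]]))
        boots[method] = bootstrap_roc(
            per_mosaic, n_boot=cfg.n_boot, seed=seeds["boot"]
        )
        s = np.concatenate([sg.scores[k.labeled_region()] for sg, k in per_mosaic])
        t = np.concatenate(
            [k.pixels_of(ASPECIFIC)[k.labeled_region()] for _, k in per_mosaic]
        )
        pooled[method] = masked_roc_auc(s, t)
        best_seg[method] = segs

    result = RunResult(
        config=cfg, splits=splits, train_result=tr,
        patch_accuracy=patch_acc, patch_roc=patch_roc, table=table,
        bootstrap=boots, pooled_roc=pooled,
        test_collection=by_split["test"], best_seg=best_seg,
    )
    if wd is not None:
        _persist(result, patches, splits, wd, seeds)
    return result


def _pooled_dice(segs, masks) -> DiceSweep:
    from .evaluation import dice_sweep_arrays

    scores = np.concatenate([s.scores[m.labeled_region()] for s, m in zip(segs, masks)])
    truth = np.concatenate(
        [m.pixels_of(ASPECIFIC)[m.labeled_region()] for m in masks]
    )
    region = np.ones_like(truth, dtype=bool)
    return dice_sweep_arrays(scores, truth, region)


def _persist(result: RunResult, patches, splits, wd: Path, seeds) -> None:
    save_checkpoint(wd / "model.npz", result.train_result.model)
    all_patches = [p for ps in patches.values() for p in ps]
    write_manifest_csv(
        wd / "manifest.csv", patch_manifest_rows(all_patches, splits)
    )
    rows = [
        {
            "cam_method": r.cam_method, "step": r.step,
            "sigma": "" if r.sigma is None else r.sigma,
            "auc": "" if r.auc is None else f"{r.auc:.4f}",
            "best_dice": f"{r.best_dice:.4f}",
            "best_threshold": f"{r.best_threshold:.2f}",
        }
        for r in result.table
    ]
    write_manifest_csv(wd / "results.csv", rows)
    for method, segs in result.best_seg.items():
        for (mosaic, _), seg in zip(result.test_collection, segs):
            save_segmentation(wd / f"seg_{method}_{mosaic.patient_id}", seg)
    (wd / "summary.json").write_text(
        json.dumps(
            {
                "seeds": seeds,
                "patch_accuracy": result.patch_accuracy,
                "patch_auc": result.patch_roc.auc,
                "best_epoch": result.train_result.best_epoch,
                "split_counts": result.splits.counts,
            },
            indent=1,
        )
    )


def render_overlay(
    mosaic: Mosaic | np.ndarray,
    seg: SegmentationMap | np.ndarray,
    mask: LabelMask | None = None,
    alpha: float = 0.45,
) -> np.ndarray:
    """Blue-to-red heatmap alpha-blended over the grayscale mosaic.

    With ``mask`` given, unlabeled pixels show the plain grayscale image
    (the labeled-area-only display variant).  Returns an (H, W, 3) uint8
    image.
    """
    pixels = mosaic.pixels if isinstance(mosaic, Mosaic) else np.asarray(mosaic)
    scores = seg.scores if isinstance(seg, SegmentationMap) else np.asarray(seg)
    if pixels.shape != scores.shape:
        raise ValueError("mosaic and score shapes differ")
    gray = np.repeat(np.clip(pixels, 0, 1)[..., None], 3, axis=2)
    heat = colormaps["jet"](np.clip(scores, 0, 1))[..., :3]
    out = (1.0 - alpha) * gray + alpha * heat
    if mask is not None:
        if mask.shape != pixels.shape:
            raise ValueError("mask shape differs from mosaic")
        unl = ~mask.labeled_region()
        out[unl] = gray[unl]
    return np.rint(out * 255.0).astype(np.uint8)


def run_config_from_yaml(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML mapping of (nested) field overrides."""
    from .synth import NoiseParams, TextureParams

    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "spec" in data:
        sd = dict(data["spec"])
        if "texture_params" in sd:
            tp = dict(sd["texture_params"])
            if "noise" in tp:
                tp["noise"] = NoiseParams(**tp["noise"])
            sd["texture_params"] = TextureParams(**tp)
        if "mosaic_shape" in sd:
            sd["mosaic_shape"] = tuple(sd["mosaic_shape"])
        kwargs["spec"] = SyntheticSpec(**sd)
    if "augment" in data:
        kwargs["augment"] = AugmentConfig(**data["augment"])
    if "train" in data:
        kwargs["train"] = TrainConfig(**data["train"])
    if "sweep" in data:
        sw = dict(data["sweep"])
        for key in ("steps", "cam_methods"):
            if key in sw:
                sw[key] = tuple(sw[key])
        if "sigmas" in sw:
            sw["sigmas"] = tuple(None if s is None else float(s) for s in sw["sigmas"])
        kwargs["sweep"] = SweepSpec(**sw)
    for key in ("downsample_factor", "patch_size", "quota_per_subclass",
                "n_boot", "seed"):
        if key in data:
            kwargs[key] = data[key]
    if "split_ratios" in data:
        kwargs["split_ratios"] = tuple(data["split_ratios"])
    return RunConfig(**kwargs)
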