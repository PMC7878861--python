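"""Sliding-window CAM inference stitched into mosaic-level score maps.

Each window of the mosaic is classified and its CAM computed; the window's
contribution is p * C, the aspecific probability times the normalized CAM
(boosting maps from aspecific windows, suppressing benign ones).
Contributions at overlapping pixels are combined as a weighted average,
with either uniform weights (plain averaging) or a 2-D Gaussian kernel

    g(x, y) = N(x; 0, sigma1) * N(y; 0, sigma2)

centered on the window, which favours each window's center where the
classifier has full spatial context.  Accumulation is streaming — two
mosaic-sized rasters (score*weight and weight) — so windows may be
processed in any order or batch; the result is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import TinyCNN, sigmoid
from .cam import CamMap, normalize_map, scorecam, traditional_cam_raw, upsample_bilinear
from .synth import Mosaic


@dataclass(frozen=True)
class StitchConfig:
    """Sliding-window geometry and blending choices."""

    window: int = 256
    step: int = 50
    weighting: str = "gaussian"           # "uniform" | "gaussian"
    sigma: tuple[float, float] = (5.0, 5.0)
    cam_method: str = "cam"               # "cam" | "scorecam"
    scorecam_layer: str = "conv3"
    batch_size: int = 32

    def validate(self) -> None:
        if not (1 <= self.step <= self.window):
            raise ValueError("step must lie in [1, window]")
        if self.weighting not in ("uniform", "gaussian"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.weighting == "gaussian" and min(self.sigma) <= 0:
            raise ValueError("sigma must be positive for gaussian weighting")
        if self.cam_method not in ("cam", "scorecam"):
            raise ValueError(f"unknown cam method {self.cam_method!r}")


@dataclass
class SegmentationMap:
    """Mosaic-shaped aspecific score map plus its weight accumulator."""

    scores: np.ndarray
    weight_sum: np.ndarray
    config: StitchConfig


def gaussian_kernel(
    window: int, sigma: float | tuple[float, float]
) -> np.ndarray:
    """Separable 2-D Gaussian window weights.

    Pixel offsets are measured from the window's continuous center
    ``(window - 1) / 2`` so the kernel is exactly mirror-symmetric; for odd
    windows the central pixel sits at offset zero with value
    ``1 / (2 pi sigma1 sigma2)``.  The kernel is *not* renormalized to sum
    to one: only weight ratios matter after the per-pixel division.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if np.isscalar(sigma):
        s1 = s2 = float(sigma)  # type: ignore[arg-type]
    else:
        s1, s2 = (float(s) for s in sigma)  # type: ignore[misc]
    if s1 <= 0 or s2 <= 0:
        raise ValueError("sigma must be positive")
    offsets = np.arange(window, dtype=np.float64) - (window - 1) / 2.0

    def pdf(x, s):
        return np.exp(-0.5 * (x / s) ** 2) / np.sqrt(2.0 * np.pi * s**2)

    return np.outer(pdf(offsets, s1), pdf(offsets, s2))


def _axis_positions(dim: int, window: int, step: int) -> list[int]:
    last = dim - window
    pos = list(range(0, last + 1, step))
    if pos[-1] != last:
        pos.append(last)  # flush final window so every pixel is covered
    return pos


def window_grid(
    mosaic_shape: tuple[int, int], window: int, step: int
) -> list[tuple[int, int]]:
    """Top-left corners of the overlapping sliding-window grid.

    Regular positions 0, step, 2*step, ... plus a flush position at
    ``dim - window`` when the regular grid does not land there, so every
    pixel is covered by at least one window.
    """
    h, w = mosaic_shape
    if h < window or w < window:
        raise ValueError(
            f"mosaic {mosaic_shape} smaller than window {window}"
        )
    if not (1 <= step <= window):
        raise ValueError("step must lie in [1, window]")
    ys = _axis_positions(h, window, step)
    xs = _axis_positions(w, window, step)
    return [(y, x) for y in ys for x in xs]


def _patch_contributions_cam(
    model: TinyCNN, patches: np.ndarray, window: int
) -> np.ndarray:
    """p * C for a batch of patches under the traditional CAM method."""
    acts = model.activations(patches)
    feats, logits = acts["features"], np.atleast_1d(acts["logit"])
    head = model.head
    out = np.empty((len(patches), window, window))
    for i in range(len(patches)):
        raw = traditional_cam_raw(feats[i], head)
        cam01 = upsample_bilinear(normalize_map(raw), (window, window))
        out[i] = float(sigmoid(logits[i])) * cam01
    return out


def _patch_contribution_scorecam(
    model: TinyCNN, patch: np.ndarray, layer: str
) -> np.ndarray:
    p = float(model.predict_proba(patch[None])[0])
    cmap: CamMap = scorecam(model, patch, layer=layer)
    return p * cmap.values


def stitch_kernel(cfg: StitchConfig) -> np.ndarray:
    """Per-window blending weights for a stitch configuration.

    Gaussian kernels are max-normalized (uniform scaling cancels in the
    weighted average) and floored at the smallest positive float: for
    narrow kernels the corner weights of large windows underflow, and a
    pixel covered only by window corners would otherwise divide zero by
    zero.
    """
    win = cfg.window
    if cfg.weighting == "gaussian":
        kernel = gaussian_kernel(win, cfg.sigma)
        return np.maximum(kernel / kernel.max(), np.finfo(np.float64).tiny)
    return np.ones((win, win))


def compute_contributions(
    model: TinyCNN,
    pixels: np.ndarray,
    positions: list[tuple[int, int]],
    window: int,
    cam_method: str = "cam",
    scorecam_layer: str = "conv3",
    batch_size: int = 32,
) -> dict[tuple[int, int], np.ndarray]:
    """p * CAM contribution of each window, keyed by top-left position.

    Contributions depend only on the window content and CAM method —
    never on step size or blending weights — so one pass over the union
    grid can serve a whole sweep of stitch configurations.
    """
    out: dict[tuple[int, int], np.ndarray] = {}
    if cam_method == "cam":
        for i in range(0, len(positions), batch_size):
            chunk = positions[i : i + batch_size]
            patches = np.stack(
                [pixels[y : y + window, x : x + window] for y, x in chunk]
            )
            contribs = _patch_contributions_cam(model, patches, window)
            out.update(zip(chunk, contribs))
    elif cam_method == "scorecam":
        for y, x in positions:
            out[(y, x)] = _patch_contribution_scorecam(
                model, pixels[y : y + window, x : x + window], scorecam_layer
            )
    else:
        raise ValueError(f"unknown cam method {cam_method!r}")
    return out


def accumulate_contributions(
    mosaic_shape: tuple[int, int],
    contributions: dict[tuple[int, int], np.ndarray],
    positions: list[tuple[int, int]],
    kernel: np.ndarray,
    cfg: StitchConfig,
) -> SegmentationMap:
    """Streamed weighted-average accumulation over the given windows."""
    acc = np.zeros(mosaic_shape)
    wsum = np.zeros(mosaic_shape)
    win = kernel.shape[0]
    for y, x in positions:
        acc[y : y + win, x : x + win] += contributions[(y, x)] * kernel
        wsum[y : y + win, x : x + win] += kernel
    return SegmentationMap(scores=acc / wsum, weight_sum=wsum, config=cfg)


def segment_mosaic(
    model: TinyCNN, mosaic: Mosaic | np.ndarray, cfg: StitchConfig
) -> SegmentationMap:
    """Stitch per-window p * CAM contributions into a mosaic score map.

    The mosaic must already be at the training scale (downsampled).  The
    final score at each pixel is the kernel-weighted average of all
    covering windows' contributions, hence lies in [0, 1].
    """
    cfg.validate()
    pixels = mosaic.pixels if isinstance(mosaic, Mosaic) else np.asarray(mosaic)
    grid = window_grid(pixels.shape, cfg.window, cfg.step)
    contribs = compute_contributions(
        model, pixels, grid, cfg.window, cfg.cam_method,
        cfg.scorecam_layer, cfg.batch_size,
    )
    return accumulate_contributions(
        pixels.shape, contribs, grid, stitch_kernel(cfg), cfg
    )
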