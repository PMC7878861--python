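"""Class-activation-map generation: traditional CAM and ScoreCAM.

Traditional CAM bypasses the GAP layer and forms the weighted sum of the
final convolutional feature maps with the head weights,

    R(x, y) = sum_k w_k A^k(x, y),

then min–max normalizes (constant maps go to all-zeros) and bilinearly
upsamples to the patch size.  Because GAP commutes with the weighted sum,
the spatial mean of the raw map equals the classifier logit minus the
head bias — the identity that makes the construction valid.

ScoreCAM replaces the head weights with forward-pass evidence: each
activation map is normalized, upsampled and used as a mask on the input
(M^k = A^k ∘ I); the masked inputs are pushed through the network and the
target-class outputs, softmaxed over channels, become the channel scores

    A_tot = sum_k S_k A^k,   S = softmax over k,

followed by a pixel-wise ReLU and min–max normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .backbone import ClassifierHead, TinyCNN


@dataclass
class CamMap:
    """Normalized per-pixel relevance map for one patch.

    ``values`` lie in [0, 1] at the patch resolution; ``raw_mean`` keeps
    the spatial mean of the pre-normalization map (traditional CAM only),
    ``channel_scores`` the simplex-normalized S_k (ScoreCAM only).
    """

    values: np.ndarray
    method: str                      # "cam" | "scorecam"
    target_class: str = "aspecific"
    raw_mean: float | None = None
    channel_scores: np.ndarray | None = None
    all_nonpositive: bool = False
    meta: dict = field(default_factory=dict)


def normalize_map(raw: np.ndarray, mode: str = "minmax01") -> np.ndarray:
    """Min–max normalization; a constant input maps to all-zeros.

    ``display255`` additionally scales to 0–255 and rounds to uint8.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("map contains non-finite values")
    lo, hi = raw.min(), raw.max()
    out = np.zeros_like(raw) if hi == lo else (raw - lo) / (hi - lo)
    if mode == "minmax01":
        return out
    if mode == "display255":
        return np.rint(out * 255.0).astype(np.uint8)
    raise ValueError(f"unknown normalization mode {mode!r}")


def upsample_bilinear(values: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling; preserves the [min, max] bounds of the input."""
    if values.shape == tuple(out_size):
        return values
    return resize(
        values, out_size, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )


def traditional_cam_raw(
    features: np.ndarray, head: ClassifierHead, target_class: str = "aspecific"
) -> np.ndarray:
    """Un-normalized weighted sum R = sum_k w_k A^k at feature resolution.

    For the benign target the binary head's weight vector is negated.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3:
        raise ValueError("features must be a (K, h, w) stack")
    w = np.asarray(head.weights, dtype=np.float64)
    if w.shape[0] != features.shape[0]:
        raise ValueError(
            f"head has {w.shape[0]} weights but features have "
            f"{features.shape[0]} channels"
        )
    if target_class == "benign":
        w = -w
    elif target_class != "aspecific":
        raise ValueError(f"unknown target class {target_class!r}")
    return np.tensordot(w, features, axes=(0, 0))


def traditional_cam(
    features: np.ndarray,
    head: ClassifierHead,
    target_class: str = "aspecific",
    out_size: tuple[int, int] | None = None,
) -> CamMap:
    """Traditional CAM: weighted sum, min–max normalize, bilinear upsample."""
    raw = traditional_cam_raw(features, head, target_class)
    norm = normalize_map(raw)
    if out_size is not None:
        norm = upsample_bilinear(norm, out_size)
    return CamMap(
        values=norm, method="cam", target_class=target_class,
        raw_mean=float(raw.mean()),
    )


def _channel_normalize(acts: np.ndarray, mode: str) -> np.ndarray:
    """Normalize each activation channel so it can act as a [0,1] mask."""
    if mode == "minmax":
        lo = acts.min(axis=(1, 2), keepdims=True)
        hi = acts.max(axis=(1, 2), keepdims=True)
        span = hi - lo
        out = np.where(span > 0, (acts - lo) / np.where(span > 0, span, 1.0), 0.0)
        return out
    if mode == "softmax":
        # spatial softmax within each channel
        z = acts - acts.max(axis=(1, 2), keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=(1, 2), keepdims=True)
    raise ValueError(f"unknown channel normalization {mode!r}")


def scorecam(
    model: TinyCNN,
    image: np.ndarray,
    target_class: str = "aspecific",
    layer: str = "conv3",
    channel_norm: str = "minmax",
    batch_size: int = 32,
) -> CamMap:
    """ScoreCAM for one patch.

    Phase 1: run the image through the network, take the K activation maps
    at ``layer``, normalize each channel and upsample to the image size.
    Phase 2: mask the input with each map (Hadamard product), forward all
    masked inputs, softmax the target-class outputs over channels into
    scores S_k, and return ReLU(sum_k S_k A^k) min–max normalized.

    If every pixel of the weighted sum is non-positive the returned map is
    all-zero and flagged via ``all_nonpositive``.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("image must be a 2-D grayscale raster")
    if layer not in model.LAYER_NAMES:
        raise ValueError(
            f"unknown layer {layer!r}; expected one of {model.LAYER_NAMES}"
        )
    if target_class not in ("aspecific", "benign"):
        raise ValueError(f"unknown target class {target_class!r}")
    acts = model.activations(image[None])[layer][0]  # (K, h, w)
    K = acts.shape[0]
    norm_acts = _channel_normalize(acts, channel_norm)
    up = np.stack(
        [upsample_bilinear(norm_acts[k], image.shape) for k in range(K)]
    )
    masked = up * image[None]  # M^k = A^k ∘ I
    logits = np.empty(K)
    for i in range(0, K, batch_size):
        logits[i : i + batch_size] = model.activations(
            masked[i : i + batch_size]
        )["logit"]
    if target_class == "benign":
        logits = -logits
    z = logits - logits.max()
    scores = np.exp(z)
    scores /= scores.sum()
    a_tot = np.tensordot(scores, up, axes=(0, 0))
    a_tot = np.maximum(a_tot, 0.0)
    flag = bool(a_tot.max() <= 0.0)
    return CamMap(
        values=normalize_map(a_tot), method="scorecam", target_class=target_class,
        channel_scores=scores, all_nonpositive=flag,
        meta={"layer": layer, "channel_norm": channel_norm},
    )
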