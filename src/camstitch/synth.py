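"""Synthetic confocal-style mosaics with partial pixel annotations.

Real reflectance-confocal mosaics of the dermal–epidermal junction are
large grayscale rasters in which architecturally preserved ("benign")
tissue shows quasi-periodic bright ring/mesh lattices, while "aspecific"
tissue loses that regularity and appears as disordered broadband speckle.
This module emulates that structure procedurally:

* two texture families — a band-pass (dominant spatial frequency) lattice
  for the benign group and a low-pass disordered speckle for aspecific —
  with configurable contrast and mean-intensity offset;
* labeled regions drawn as smoothed random blobs (top quantiles of
  Gaussian-filtered noise fields), giving the soft, ill-defined region
  borders typical of tissue rather than polygonal ones;
* a configurable unlabeled fraction; unlabeled areas receive a random
  mixture of both textures so that evaluation masking is genuinely
  exercised downstream;
* multiplicative speckle noise and Gaussian blur as imaging noise.

Per-class pixel fractions are hit essentially exactly (quantile
construction), every mosaic carries a distinct patient id, and generation
is bit-deterministic given ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, stats

from .labels import (
    ASPECIFIC,
    BENIGN_LABELS,
    FINE_LABELS,
    LABEL_TO_INDEX,
    UNLABELED,
)

# Fine-label shares of *labeled* pixels mirroring the clinical class
# distribution (ring 34, artifact 17, mesh 17, background 14, aspecific 12,
# nest 5 — in percent of labeled pixels), scaled so that 38% of all pixels
# are labeled.
_LABELED_SHARES = {
    "ring": 0.34,
    "artifact": 0.17,
    "mesh": 0.17,
    "background": 0.14,
    "aspecific": 0.12,
    "nest": 0.05,
}
_TOTAL_LABELED = 0.38
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    k: _TOTAL_LABELED * v / sum(_LABELED_SHARES.values())
    for k, v in _LABELED_SHARES.items()
}


@dataclass(frozen=True)
class NoiseParams:
    """Imaging-noise model: multiplicative speckle then Gaussian blur."""

    speckle_variance: float = 0.01
    blur_sigma: float = 1.0

    def validate(self) -> None:
        if self.speckle_variance < 0 or self.blur_sigma < 0:
            raise InvalidSpecError("noise parameters must be non-negative")


@dataclass(frozen=True)
class TextureParams:
    """Descriptors of the two procedural texture families.

    ``benign_period`` is the dominant spatial wavelength (pixels at full
    resolution) of the quasi-periodic lattice; ``aspecific_corr`` the
    correlation length of the disordered speckle.  ``*_mean`` /
    ``*_contrast`` set first- and second-order intensity statistics; a
    nonzero mean offset between the families makes the downstream binary
    task learnable at desk scale.
    """

    benign_period: float = 32.0
    benign_contrast: float = 0.22
    benign_mean: float = 0.58
    aspecific_corr: float = 10.0
    aspecific_contrast: float = 0.22
    aspecific_mean: float = 0.40
    noise: NoiseParams = field(default_factory=NoiseParams)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for a batch of synthetic annotated mosaics."""

    mosaic_shape: tuple[int, int] = (2048, 2048)
    class_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    texture_params: TextureParams = field(default_factory=TextureParams)
    blob_sigma: float = 48.0
    n_mosaics: int = 12
    patient_prefix: str = "P"

    @property
    def unlabeled_fraction(self) -> float:
        return 1.0 - sum(self.class_fractions.values())

    @property
    def patients(self) -> list[str]:
        """One distinct patient id per mosaic."""
        return [f"{self.patient_prefix}{i:03d}" for i in range(self.n_mosaics)]

    def validate(self) -> None:
        fr = self.class_fractions
        if any(v < 0 for v in fr.values()):
            raise InvalidSpecError("class fractions must be non-negative")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise InvalidSpecError("class fractions must sum to at most 1")
        unknown = set(fr) - set(FINE_LABELS)
        if unknown:
            raise InvalidSpecError(f"unknown labels in class_fractions: {unknown}")
        h, w = self.mosaic_shape
        if min(h, w) < max(32, int(self.blob_sigma)):
            raise InvalidSpecError(
                f"mosaic shape {self.mosaic_shape} smaller than minimum blob size"
            )
        self.texture_params.noise.validate()

    def easy(self) -> "SyntheticSpec":
        """High texture-contrast variant (strongly separable families)."""
        tex = replace(
            self.texture_params,
            benign_mean=0.62, aspecific_mean=0.33,
            benign_contrast=0.18, aspecific_contrast=0.18,
        )
        return replace(self, texture_params=tex)


class InvalidSpecError(ValueError):
    """Raised when a synthetic-data recipe violates its invariants."""


@dataclass
class Mosaic:
    """A single-channel grayscale raster in [0, 1] with provenance."""

    pixels: np.ndarray
    patient_id: str
    pixel_pitch: float = 1.0  # physical size per pixel; metadata only

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class LabelMask:
    """Per-pixel categorical annotation aligned with a :class:`Mosaic`.

    Stored as a uint8 raster of palette indices (see ``labels.LABEL_TO_INDEX``).
    """

    labels: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def pixels_of(self, label: str) -> np.ndarray:
        """Boolean raster of pixels annotated with ``label``."""
        return self.labels == LABEL_TO_INDEX[label]

    def labeled_region(self) -> np.ndarray:
        """Boolean raster of all annotated (non-unlabeled) pixels."""
        return self.labels != LABEL_TO_INDEX[UNLABELED]

    def fraction(self, label: str) -> float:
        return float(self.pixels_of(label).mean())


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    sd = f.std()
    return f / sd if sd > 0 else f


def _bandpass_texture(shape, period: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic lattice: white noise filtered by an annular band-pass
    centered at spatial frequency 1/period."""
    h, w = shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    r = np.sqrt(fy**2 + fx**2)
    f0 = 1.0 / period
    band = np.exp(-((r - f0) ** 2) / (2 * (0.35 * f0) ** 2))
    spec = np.fft.fft2(rng.standard_normal(shape)) * band
    tex = np.real(np.fft.ifft2(spec))
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _speckle_texture(shape, corr: float, rng: np.random.Generator) -> np.ndarray:
    """Disordered broadband speckle: low-pass filtered noise, rectified to
    give the granular bright-dot statistics of incoherent speckle."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr / 4.0, mode="wrap")
    tex = np.abs(f)
    tex -= tex.mean()
    sd = tex.std()
    return tex / sd if sd > 0 else tex


def _family_textures(spec: SyntheticSpec, rng: np.random.Generator):
    tp = spec.texture_params
    benign = tp.benign_mean + tp.benign_contrast * _bandpass_texture(
        spec.mosaic_shape, tp.benign_period, rng
    )
    aspec = tp.aspecific_mean + tp.aspecific_contrast * _speckle_texture(
        spec.mosaic_shape, tp.aspecific_corr, rng
    )
    return np.clip(benign, 0.0, 1.0), np.clip(aspec, 0.0, 1.0)


def generate_labeled_mosaic(
    spec: SyntheticSpec, seed: int, patient_id: str | None = None
) -> tuple[Mosaic, LabelMask]:
    """Generate one annotated mosaic.

    Labeled regions are connected smooth blobs (top quantiles of per-class
    Gaussian random fields) filled with the class's texture family;
    remaining pixels are unlabeled and carry a random spatial mixture of
    both families.  Deterministic given ``(spec, seed)``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    h, w = spec.mosaic_shape
    n = h * w

    mask = np.full((h, w), LABEL_TO_INDEX[UNLABELED], dtype=np.uint8)
    unassigned = np.ones(n, dtype=bool)
    order = list(FINE_LABELS)
    rng.shuffle(order)
    for label in order:
        frac = spec.class_fractions.get(label, 0.0)
        count = int(round(frac * n))
        if count == 0:
            continue
        fld = _smooth_field((h, w), spec.blob_sigma, rng).ravel()
        cand = np.flatnonzero(unassigned)
        take = cand[np.argsort(fld[cand])[::-1][:count]]
        mask.ravel()[take] = LABEL_TO_INDEX[label]
        unassigned[take] = False

    benign_tex, aspec_tex = _family_textures(spec, rng)
    benign_family = np.isin(
        mask, [LABEL_TO_INDEX[l] for l in BENIGN_LABELS]
    )
    aspec_family = mask == LABEL_TO_INDEX[ASPECIFIC]
    # unlabeled areas: random mixture of the two families
    mix = _smooth_field((h, w), spec.blob_sigma, rng) > 0
    pixels = np.where(
        benign_family | ((~aspec_family) & (~benign_family) & mix),
        benign_tex,
        aspec_tex,
    )

    noisy = apply_imaging_noise(
        pixels, spec.texture_params.noise, seed=int(rng.integers(0, 2**31 - 1))
    )
    pid = patient_id if patient_id is not None else f"{spec.patient_prefix}{seed:03d}"
    return Mosaic(pixels=noisy, patient_id=pid), LabelMask(labels=mask)


def generate_collection(
    spec: SyntheticSpec, seed: int
) -> list[tuple[Mosaic, LabelMask]]:
    """Generate ``spec.n_mosaics`` mosaics, one distinct patient each."""
    spec.validate()
    rng = np.random.default_rng(seed)
    out = []
    for pid in spec.patients:
        sub = int(rng.integers(0, 2**31 - 1))
        out.append(generate_labeled_mosaic(spec, sub, patient_id=pid))
    return out


def apply_imaging_noise(
    mosaic: np.ndarray | Mosaic, noise: NoiseParams, seed: int
) -> np.ndarray | Mosaic:
    """Multiplicative speckle (mean-one) followed by Gaussian blur, clipped
    to [0, 1].  Zero variance and zero blur is the identity."""
    noise.validate()
    is_mosaic = isinstance(mosaic, Mosaic)
    pixels = mosaic.pixels if is_mosaic else mosaic
    out = np.asarray(pixels, dtype=np.float64)
    if noise.speckle_variance > 0:
        rng = np.random.default_rng(seed)
        out = out * (
            1.0 + np.sqrt(noise.speckle_variance) * rng.standard_normal(out.shape)
        )
    if noise.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, noise.blur_sigma, mode="nearest")
    if noise.speckle_variance > 0 or noise.blur_sigma > 0:
        out = np.clip(out, 0.0, 1.0)
    if is_mosaic:
        return Mosaic(pixels=out, patient_id=mosaic.patient_id,
                      pixel_pitch=mosaic.pixel_pitch)
    return out


def texture_separation(spec: SyntheticSpec, seed: int, n_pixels: int = 50_000) -> float:
    """Two-sample Kolmogorov–Smirnov statistic between the pixel-intensity
    distributions of the two texture families (after imaging noise).

    Used as the learnability floor for the downstream classification task:
    larger values mean more separable families.
    """
    rng = np.random.default_rng(seed)
    benign, aspec = _family_textures(spec, rng)
    benign = apply_imaging_noise(benign, spec.texture_params.noise, seed + 1)
    aspec = apply_imaging_noise(aspec, spec.texture_params.noise, seed + 2)
    idx = rng.choice(benign.size, size=min(n_pixels, benign.size), replace=False)
    return float(stats.ks_2samp(benign.ravel()[idx], aspec.ravel()[idx]).statistic)
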