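"""Disk formats: float TIFF mosaics, paletted PNG masks, sidecar metadata.

Mosaics are written as single-channel float32 TIFF; label masks as
paletted PNG using the fixed label -> index table in :mod:`.labels`; each
artifact gets a YAML or JSON sidecar recording the spec and seeds so
everything on disk is traceable to its configuration.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .labels import MASK_PALETTE
from .stitch import SegmentationMap
from .synth import LabelMask, Mosaic


def save_mosaic(path: str | Path, mosaic: Mosaic) -> None:
    tifffile.imwrite(
        str(path), mosaic.pixels.astype(np.float32),
        metadata={"patient_id": mosaic.patient_id,
                  "pixel_pitch": mosaic.pixel_pitch},
    )


def load_mosaic(path: str | Path, patient_id: str | None = None) -> Mosaic:
    with tifffile.TiffFile(str(path)) as tf:
        pixels = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return Mosaic(
        pixels=pixels,
        patient_id=patient_id or str(meta.get("patient_id", Path(path).stem)),
        pixel_pitch=float(meta.get("pixel_pitch", 1.0)),
    )


def save_mask(path: str | Path, mask: LabelMask) -> None:
    img = Image.fromarray(mask.labels, mode="P")
    palette = [c for rgb in MASK_PALETTE for c in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(str(path))


def load_mask(path: str | Path) -> LabelMask:
    return LabelMask(labels=np.asarray(Image.open(str(path)), dtype=np.uint8))


def save_sidecar(path: str | Path, payload: dict) -> None:
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_sidecar(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_segmentation(path_stem: str | Path, seg: SegmentationMap) -> None:
    """Float TIFF of scores plus a JSON sidecar echoing the stitch config."""
    stem = Path(path_stem)
    tifffile.imwrite(str(stem.with_suffix(".tif")),
                     seg.scores.astype(np.float32))
    stem.with_suffix(".json").write_text(
        json.dumps(asdict(seg.config), default=list, indent=1)
    )


def write_manifest_csv(path: str | Path, rows: list[dict]) -> None:
    if not rows:
        Path(path).write_text("")
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)


def save_overlay_png(path: str | Path, rgb: np.ndarray) -> None:
    Image.fromarray(rgb).save(str(path))
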