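"""Label vocabulary shared across the package.

Mosaics are annotated with six morphological patterns plus an explicit
``unlabeled`` category.  Five of the six patterns (background, artifact,
mesh, nest, ring) form the *benign* group; ``aspecific`` — loss of the
regular architectural pattern — is the positive class everywhere in this
package.  Unlabeled pixels are never sampled for training and never scored
during evaluation.
"""

from __future__ import annotations

BACKGROUND = "background"
ARTIFACT = "artifact"
MESH = "mesh"
NEST = "nest"
RING = "ring"
ASPECIFIC = "aspecific"
UNLABELED = "unlabeled"

#: All seven mask categories, in fixed index order.
ALL_LABELS: tuple[str, ...] = (
    BACKGROUND, ARTIFACT, MESH, NEST, RING, ASPECIFIC, UNLABELED,
)

#: The five fine labels collapsed into the negative ("benign") weak class.
BENIGN_LABELS: tuple[str, ...] = (BACKGROUND, ARTIFACT, MESH, NEST, RING)

#: The six fine labels that can be sampled (everything except unlabeled).
FINE_LABELS: tuple[str, ...] = BENIGN_LABELS + (ASPECIFIC,)

#: Fixed label -> palette index table used for paletted-PNG mask export.
LABEL_TO_INDEX: dict[str, int] = {name: i for i, name in enumerate(ALL_LABELS)}
INDEX_TO_LABEL: dict[int, str] = {i: name for name, i in LABEL_TO_INDEX.items()}

#: RGB palette for mask PNGs (one entry per label index).
MASK_PALETTE: tuple[tuple[int, int, int], ...] = (
    (40, 40, 40),     # background
    (150, 90, 30),    # artifact
    (60, 140, 200),   # mesh
    (200, 180, 60),   # nest
    (90, 180, 90),    # ring
    (220, 60, 60),    # aspecific
    (0, 0, 0),        # unlabeled
)


def weak_label_of(fine_label: str) -> str:
    """Collapse a fine label to its weak (binary) class name."""
    if fine_label == ASPECIFIC:
        return ASPECIFIC
    if fine_label in BENIGN_LABELS:
        return "benign"
    raise ValueError(f"{fine_label!r} has no weak label")
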