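"""Core value types shared across the pipeline.

Conventions used throughout the package:

* images are 2-D ``numpy`` arrays indexed ``[row, col]``;
* bounding boxes are 0-based, half-open ``[row_min, row_max) x [col_min, col_max)``;
* class labels are ``0 = benign``, ``1 = malignant`` (malignant is the
  positive class for sensitivity/specificity);
* every model-facing ROI is exactly ``ROI_SIZE x ROI_SIZE`` pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np

#: Side length (pixels) of every model-facing ROI.
ROI_SIZE = 224

#: Base scale for the translation-based multi-context scheme: the mass crop is
#: isotropically rescaled so that its smaller side equals this many pixels.
BASE_SCALE = 256


class Label(IntEnum):
    """Pathology label of a mass region (malignant = positive class)."""

    BENIGN = 0
    MALIGNANT = 1


class Density(IntEnum):
    """BI-RADS breast-density category, fatty (I) to extremely dense (IV)."""

    I = 1
    II = 2
    III = 3
    IV = 4


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open on both axes."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self) -> None:
        if min(self.row_min, self.col_min, self.row_max, self.col_max) < 0:
            raise ValueError(f"bounding box has negative coordinates: {self}")
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError(f"bounding box is empty: {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def contains(self, other: "BoundingBox") -> bool:
        return (
            self.row_min <= other.row_min
            and self.col_min <= other.col_min
            and self.row_max >= other.row_max
            and self.col_max >= other.col_max
        )

    def within(self, image_shape: tuple[int, int]) -> bool:
        rows, cols = image_shape
        return self.row_max <= rows and self.col_max <= cols

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.row_min, self.col_min, self.row_max, self.col_max)


@dataclass
class GrayImage:
    """Single-channel intensity image with an explicit bit depth."""

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError(f"expected a non-empty 2-D array, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class MassRegion:
    """A mammogram (or synthetic phantom) with one annotated mass.

    The mass is assumed to be already segmented: ``bbox`` is the tight
    bounding box of the lesion.  ``label`` and ``density`` may be ``None``
    at inference time.
    """

    image: GrayImage
    bbox: BoundingBox
    label: Optional[Label] = None
    density: Optional[Density] = None
    region_id: str = ""

    def __post_init__(self) -> None:
        if not self.bbox.within(self.image.shape):
            raise ValueError(
                f"bbox {self.bbox} lies outside image of shape {self.image.shape}"
            )

    def crop(self, bbox: Optional[BoundingBox] = None) -> np.ndarray:
        """Pixel crop of ``bbox`` (defaults to the mass bounding box)."""
        b = bbox if bbox is not None else self.bbox
        return self.image.pixels[b.row_min : b.row_max, b.col_min : b.col_max]


@dataclass(frozen=True)
class Provenance:
    """Where an ROI came from: extraction scheme plus scheme-specific detail."""

    scheme: str  # "scale" | "context" | "window" | "orient"
    index: int
    scale_percent: Optional[float] = None
    crop_position: Optional[str] = None
    flipped: bool = False
    angle: int = 0


@dataclass
class ROI:
    """A fixed-size model-input patch with full provenance."""

    pixels: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (ROI_SIZE, ROI_SIZE):
            raise ValueError(
                f"ROI must be {ROI_SIZE}x{ROI_SIZE}, got {self.pixels.shape}"
            )


@dataclass
class ROISet:
    """Ordered, deterministic collection of ROIs from one mass region.

    The ordering is part of the contract: stacked fusion builds its feature
    vector positionally from this sequence.
    """

    rois: list[ROI] = field(default_factory=list)
    region_ref: str = ""

    def __post_init__(self) -> None:
        if not self.rois:
            raise ValueError("ROISet may not be empty")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> ROI:
        return self.rois[i]

    def pixel_stack(self) -> np.ndarray:
        """All ROI pixel arrays stacked to shape ``(n, ROI_SIZE, ROI_SIZE)``."""
        return np.stack([r.pixels for r in self.rois])


def as_labels(values: Sequence) -> np.ndarray:
    """Coerce a sequence of labels/ints to an int array of 0/1."""
    out = np.asarray([int(v) for v in values], dtype=int)
    if out.size and not np.isin(out, (0, 1)).all():
        raise ValueError("labels must be 0 (benign) or 1 (malignant)")
    return out
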