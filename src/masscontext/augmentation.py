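"""Training-set augmentation: multi-context windows, orientations, scales.

Mass datasets with pathology labels are small (hundreds of regions per
class), far too few to fine-tune a CNN.  Three augmentation families are
generated from each labeled region and their union forms the training
set:

* **multi-context**: a fixed-size window that always inscribes the whole
  mass slides over the image in 10-px strides;
* **multi-orientation**: each window is rotated through {0, 90, 180,
  270} degrees and each rotation optionally flipped horizontally
  (8 variants — lossless array transpositions);
* **multi-scale**: the bounding box expanded by 5% and 10% per edge.

Counts are closed-form, the output order is deterministic, and labels are
inherited unchanged from the source region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .datatypes import ROI, ROI_SIZE, BoundingBox, MassRegion, Provenance
from .roi_context import expand_bbox, resize_bilinear

__all__ = [
    "AugmentationPlan",
    "sliding_window_crops",
    "sliding_window_count",
    "orientation_variants",
    "build_training_set",
    "AugmentedSample",
]

DEFAULT_STRIDE = 10
DEFAULT_ANGLES = (0, 90, 180, 270)
DEFAULT_SCALE_PERCENTS = (5.0, 10.0)
#: Margin (px) added to the longer bbox side to set the sliding-window size.
WINDOW_MARGIN = 20


@dataclass
class AugmentationPlan:
    """Declarative description of the augmentation to perform."""

    stride: int = DEFAULT_STRIDE
    angles: tuple[int, ...] = DEFAULT_ANGLES
    flip: bool = True
    scale_percents: tuple[float, ...] = DEFAULT_SCALE_PERCENTS
    window_margin: int = WINDOW_MARGIN
    compose_orientations: bool = True  # orientations applied to window crops
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if any(a % 90 != 0 for a in self.angles):
            raise ValueError("angles must be multiples of 90 degrees")


def _offset_range(lo_limit: int, hi_limit: int) -> tuple[int, int]:
    """Valid window offsets [lo, hi] on one axis, or raise if empty."""
    if hi_limit < lo_limit:
        raise ValueError("window cannot simultaneously contain bbox and image")
    return lo_limit, hi_limit


def _axis_offsets(
    bbox_lo: int, bbox_hi: int, win: int, extent: int, stride: int
) -> list[int]:
    """Offsets o (multiples of ``stride`` above the minimum valid offset)
    such that [o, o+win) contains [bbox_lo, bbox_hi) and stays in
    [0, extent)."""
    lo = max(0, bbox_hi - win)
    hi = min(bbox_lo, extent - win)
    lo, hi = _offset_range(lo, hi)
    return list(range(lo, hi + 1, stride))


def sliding_window_count(
    bbox: BoundingBox,
    image_shape: tuple[int, int],
    window: tuple[int, int],
    stride: int = DEFAULT_STRIDE,
) -> int:
    """Closed-form count of sliding windows: ``(floor(dr/stride)+1) *
    (floor(dc/stride)+1)`` over the valid offset ranges."""
    win_r, win_c = window
    rr = _axis_offsets(bbox.row_min, bbox.row_max, win_r, image_shape[0], stride)
    cc = _axis_offsets(bbox.col_min, bbox.col_max, win_c, image_shape[1], stride)
    return len(rr) * len(cc)


def sliding_window_crops(
    region: MassRegion,
    window: tuple[int, int],
    stride: int = DEFAULT_STRIDE,
) -> list[ROI]:
    """All window placements (stride-spaced) that inscribe the whole mass
    and stay inside the image, each resized to 224 x 224."""
    win_r, win_c = window
    if win_r < region.bbox.height or win_c < region.bbox.width:
        raise ValueError(
            f"window {window} smaller than mass bbox {region.bbox.shape}"
        )
    rows, cols = region.image.shape
    if win_r > rows or win_c > cols:
        raise ValueError(f"window {window} exceeds image shape {(rows, cols)}")
    b = region.bbox
    row_offs = _axis_offsets(b.row_min, b.row_max, win_r, rows, stride)
    col_offs = _axis_offsets(b.col_min, b.col_max, win_c, cols, stride)
    out = []
    idx = 0
    for r0 in row_offs:
        for c0 in col_offs:
            patch = region.image.pixels[r0 : r0 + win_r, c0 : c0 + win_c]
            out.append(
                ROI(
                    resize_bilinear(patch, (ROI_SIZE, ROI_SIZE)),
                    Provenance(
                        scheme="window", index=idx, crop_position=f"{r0},{c0}"
                    ),
                )
            )
            idx += 1
    return out


def orientation_variants(
    roi: ROI,
    angles: Sequence[int] = DEFAULT_ANGLES,
    flip: bool = True,
) -> list[ROI]:
    """Rotations (clockwise, 90-degree multiples) of a square ROI, then the
    same rotations of its horizontal flip.  All lossless."""
    out = []
    idx = 0
    for flipped in (False, True) if flip else (False,):
        base = roi.pixels[:, ::-1] if flipped else roi.pixels
        for angle in angles:
            k = (angle // 90) % 4
            # np.rot90 rotates counter-clockwise; negate for clockwise
            pixels = np.rot90(base, k=-k).copy()
            out.append(
                ROI(
                    pixels,
                    Provenance(
                        scheme="orient",
                        index=idx,
                        crop_position=roi.provenance.crop_position,
                        flipped=flipped,
                        angle=angle,
                    ),
                )
            )
            idx += 1
    return out


@dataclass
class AugmentedSample:
    """One augmented training ROI with its inherited label."""

    roi: ROI
    label: int
    source_region: str
    transform: str


def default_window(region: MassRegion, margin: int = WINDOW_MARGIN) -> tuple[int, int]:
    """Square sliding window: the bbox's longer side plus a margin, capped
    at the image size."""
    side = max(region.bbox.height, region.bbox.width) + margin
    rows, cols = region.image.shape
    return (min(side, rows), min(side, cols))


def augment_region(
    region: MassRegion, plan: AugmentationPlan | None = None
) -> list[AugmentedSample]:
    """All augmented samples for one labeled region (deterministic order)."""
    plan = plan or AugmentationPlan()
    if region.label is None:
        raise ValueError(f"region {region.region_id!r} has no label")
    label = int(region.label)
    samples: list[AugmentedSample] = []

    window = default_window(region, plan.window_margin)
    windows = sliding_window_crops(region, window, plan.stride)
    for w in windows:
        if plan.compose_orientations:
            for v in orientation_variants(w, plan.angles, plan.flip):
                desc = (
                    f"window@{w.provenance.crop_position}"
                    f"/rot{v.provenance.angle}"
                    f"{'f' if v.provenance.flipped else ''}"
                )
                samples.append(AugmentedSample(v, label, region.region_id, desc))
        else:
            samples.append(
                AugmentedSample(
                    w, label, region.region_id,
                    f"window@{w.provenance.crop_position}",
                )
            )

    for s in plan.scale_percents:
        box = expand_bbox(region.bbox, s, region.image.shape)
        patch = resize_bilinear(region.crop(box), (ROI_SIZE, ROI_SIZE))
        roi = ROI(patch, Provenance(scheme="scale", index=0, scale_percent=s))
        samples.append(
            AugmentedSample(roi, label, region.region_id, f"scale{s:g}")
        )
    return samples


def build_training_set(
    regions: Sequence[MassRegion], plan: AugmentationPlan | None = None
) -> list[AugmentedSample]:
    """Union of the three augmentation families over all labeled regions."""
    plan = plan or AugmentationPlan()
    out: list[AugmentedSample] = []
    for region in regions:
        out.extend(augment_region(region, plan))
    return out
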