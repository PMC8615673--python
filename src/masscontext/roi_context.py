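"""Test-time extraction of context-diverse ROIs around a segmented mass.

Two schemes generate several crops of the same mass with differing amounts
of surrounding tissue, so that a single CNN backbone can emit several
(diverse) opinions about one lesion:

* **scale-based** (``extract_multiscale_rois``): the mass bounding box is
  symmetrically expanded by a set of percentages; each expanded crop is
  resized (anisotropically) to 224 x 224.
* **translation-based** (``extract_multicontext_rois``): the tight crop is
  isotropically rescaled so its smaller side is 256 px, then the four
  corner 224 x 224 windows plus the center window are cropped and each is
  also flipped horizontally.  Together with the whole rescaled crop
  (resized to 224 x 224) this yields 11 ROIs.

All resizes are bilinear; output dimensions are rounded half-up.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .datatypes import (
    BASE_SCALE,
    ROI,
    ROI_SIZE,
    BoundingBox,
    GrayImage,
    MassRegion,
    Provenance,
    ROISet,
)

__all__ = [
    "expand_bbox",
    "isotropic_rescale_to_base",
    "extract_multiscale_rois",
    "extract_multicontext_rois",
    "resize_bilinear",
    "SCHEME_SCALES",
]

#: Named multi-scale schemes: per-edge expansion percentages of the bbox.
SCHEME_SCALES: dict[str, tuple[float, ...]] = {
    "MS1": (5, 10, 15, 20, 25),
    "MS2": (10, 20, 30, 40, 50),
    "MS3": (50, 60, 70, 80, 100),
}


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def resize_bilinear(pixels: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Deterministic bilinear resize preserving the intensity range."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.shape == tuple(out_shape):
        return pixels.copy()
    return _sk_resize(
        pixels, out_shape, order=1, preserve_range=True, anti_aliasing=False
    )


def expand_bbox(
    bbox: BoundingBox, percent: float, image_shape: tuple[int, int]
) -> BoundingBox:
    """Grow ``bbox`` by ``percent`` % of each side length on each of its two
    edges, clamped to the image bounds.

    A 100 x 100 box at 50% gains 50 px on every edge.  The result always
    contains the input box; clamping never shrinks it below the input.
    """
    if percent < 0:
        raise ValueError(f"percent must be non-negative, got {percent}")
    if not bbox.within(image_shape):
        raise ValueError(f"bbox {bbox} outside image of shape {image_shape}")
    dr = bbox.height * percent / 100.0
    dc = bbox.width * percent / 100.0
    rows, cols = image_shape
    return BoundingBox(
        row_min=max(0, _round_half_up(bbox.row_min - dr)),
        col_min=max(0, _round_half_up(bbox.col_min - dc)),
        row_max=min(rows, _round_half_up(bbox.row_max + dr)),
        col_max=min(cols, _round_half_up(bbox.col_max + dc)),
    )


def isotropic_rescale_to_base(
    crop: GrayImage | np.ndarray, base: int = BASE_SCALE
) -> np.ndarray:
    """Rescale so the smaller side equals ``base`` pixels, preserving aspect
    ratio (to rounding).  Returns a float array."""
    pixels = crop.pixels if isinstance(crop, GrayImage) else np.asarray(crop)
    if pixels.ndim != 2 or min(pixels.shape) < 1:
        raise ValueError(f"expected non-empty 2-D crop, got shape {pixels.shape}")
    rows, cols = pixels.shape
    factor = base / min(rows, cols)
    out_rows = base if rows <= cols else _round_half_up(rows * factor)
    out_cols = base if cols <= rows else _round_half_up(cols * factor)
    # exact square input maps to base x base
    if rows == cols:
        out_rows = out_cols = base
    return resize_bilinear(pixels, (out_rows, out_cols))


def extract_multiscale_rois(
    region: MassRegion, scales: Iterable[float]
) -> ROISet:
    """Scale-based scheme: one 224 x 224 ROI per expansion percentage,
    ordered by ascending scale."""
    scale_list = sorted(set(float(s) for s in scales))
    if not scale_list:
        raise ValueError("scales must be non-empty")
    rois = []
    for i, s in enumerate(scale_list):
        box = expand_bbox(region.bbox, s, region.image.shape)
        patch = resize_bilinear(region.crop(box), (ROI_SIZE, ROI_SIZE))
        rois.append(
            ROI(patch, Provenance(scheme="scale", index=i, scale_percent=s))
        )
    return ROISet(rois, region_ref=region.region_id)


#: Fixed emission order of the translation-based scheme.
_CONTEXT_ORDER = (
    ("full", False),
    ("top_left", False),
    ("top_right", False),
    ("bottom_left", False),
    ("bottom_right", False),
    ("center", False),
    ("top_left", True),
    ("top_right", True),
    ("bottom_left", True),
    ("bottom_right", True),
    ("center", True),
)


def _context_offsets(shape: tuple[int, int]) -> dict[str, tuple[int, int]]:
    rows, cols = shape
    dr, dc = rows - ROI_SIZE, cols - ROI_SIZE
    return {
        "top_left": (0, 0),
        "top_right": (0, dc),
        "bottom_left": (dr, 0),
        "bottom_right": (dr, dc),
        "center": (dr // 2, dc // 2),
    }


def extract_multicontext_rois(
    region: MassRegion, positions: Sequence[str] | None = None
) -> ROISet:
    """Translation-based scheme: 11 ROIs in a fixed documented order.

    Order: ``[full, TL, TR, BL, BR, C, TLf, TRf, BLf, BRf, Cf]`` where
    ``full`` is the whole rescaled crop resized to 224 x 224 and the ``f``
    suffix marks a horizontal flip.  ``positions`` restricts the crop
    positions (e.g. ``("center",)`` for the 3-context variant: full,
    center, center-flip); the whole-crop ROI is always emitted first.
    """
    rescaled = isotropic_rescale_to_base(region.crop())
    offsets = _context_offsets(rescaled.shape)
    keep = set(positions) if positions is not None else None

    rois = []
    for idx, (pos, flipped) in enumerate(_CONTEXT_ORDER):
        if pos == "full":
            patch = resize_bilinear(rescaled, (ROI_SIZE, ROI_SIZE))
        else:
            if keep is not None and pos not in keep:
                continue
            r0, c0 = offsets[pos]
            patch = rescaled[r0 : r0 + ROI_SIZE, c0 : c0 + ROI_SIZE].copy()
            if flipped:
                patch = patch[:, ::-1].copy()
        rois.append(
            ROI(
                patch,
                Provenance(
                    scheme="context", index=idx, crop_position=pos, flipped=flipped
                ),
            )
        )
    return ROISet(rois, region_ref=region.region_id)


def extract_rois(region: MassRegion, scheme: str) -> ROISet:
    """Dispatch a named test-time extraction scheme.

    ``single`` is the tight-bbox crop; ``MS1``/``MS2``/``MS3`` the scale
    schemes; ``MC1`` the 3-context and ``MC2`` the 11-ROI translation
    scheme.
    """
    if scheme == "single":
        return extract_multiscale_rois(region, (0,))
    if scheme in SCHEME_SCALES:
        return extract_multiscale_rois(region, SCHEME_SCALES[scheme])
    if scheme == "MC1":
        return extract_multicontext_rois(region, positions=("center",))
    if scheme == "MC2":
        return extract_multicontext_rois(region)
    raise ValueError(f"unknown extraction scheme {scheme!r}")


def n_rois(scheme: str) -> int:
    """Number of ROIs a named scheme emits."""
    fixed = {"single": 1, "MC1": 3, "MC2": 11}
    if scheme in fixed:
        return fixed[scheme]
    if scheme in SCHEME_SCALES:
        return len(SCHEME_SCALES[scheme])
    raise ValueError(f"unknown extraction scheme {scheme!r}")
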