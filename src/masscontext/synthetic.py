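"""Synthetic mammogram-like phantoms with one labeled mass per image.

The generator emulates just enough structure for every pipeline stage to
run and be tested without any dataset download: a textured gray
background (Gaussian-filtered noise whose energy grows with the BI-RADS
density tag) containing one bright lesion.  The two classes differ along
the visual axes radiologists use for masses:

* **benign** — a smooth ellipse with a sharp, well-circumscribed margin;
* **malignant** — a star-convex spiculated blob with a blurred margin.

No claim of clinical realism is made; the classes are separable by
construction (margin sharpness, eccentricity, spiculation) so that
learning-based stages have signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .datatypes import BoundingBox, Density, GrayImage, Label, MassRegion

__all__ = [
    "SyntheticConfig", "generate_region", "generate_dataset",
    "SyntheticDataset", "summary_features",
]

#: Background texture amplitude per density class (intensity units, 8-bit).
_TEXTURE_AMP = {Density.I: 5.0, Density.II: 9.0, Density.III: 13.0, Density.IV: 17.0}
_BACKGROUND_LEVEL = 70.0
_LESION_AMP = 95.0
_SUPPORT_THRESHOLD = 0.12  # fraction of peak profile that counts as lesion


@dataclass
class SyntheticConfig:
    """Generation parameters; defaults give two clearly separable classes."""

    image_size: tuple[int, int] = (512, 512)
    n_per_class: int = 50
    density_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    benign_axis_range: tuple[float, float] = (28.0, 50.0)
    benign_aspect_range: tuple[float, float] = (0.55, 0.85)
    benign_margin_sigma: float = 1.0
    malignant_radius_range: tuple[float, float] = (28.0, 45.0)
    malignant_spicule_range: tuple[int, int] = (8, 14)
    malignant_spicule_amp: float = 0.35
    malignant_margin_sigma: float = 4.0
    noise_sd: float = 3.0
    bit_depth: int = 8
    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if abs(sum(self.density_mix) - 1.0) > 1e-9:
            raise ValueError("density_mix must sum to 1")


def _background(
    shape: tuple[int, int], density: Density, noise_sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Low-frequency tissue texture plus pixel noise."""
    texture = ndimage.gaussian_filter(rng.normal(size=shape), sigma=8.0)
    texture *= _TEXTURE_AMP[density] / max(texture.std(), 1e-9)
    level = _BACKGROUND_LEVEL + 6.0 * (int(density) - 1)
    return level + texture + rng.normal(scale=noise_sd, size=shape)


def _benign_profile(
    shape: tuple[int, int], center: tuple[float, float],
    cfg: SyntheticConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Smooth bright ellipse with a sharp margin, in [0, 1]."""
    a = rng.uniform(*cfg.benign_axis_range)
    b = a * rng.uniform(*cfg.benign_aspect_range)
    theta = rng.uniform(0, np.pi)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    mask = ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(float)
    return ndimage.gaussian_filter(mask, sigma=cfg.benign_margin_sigma)


def _malignant_profile(
    shape: tuple[int, int], center: tuple[float, float],
    cfg: SyntheticConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Star-convex spiculated blob with a blurred margin, in [0, 1]."""
    r0 = rng.uniform(*cfg.malignant_radius_range)
    k = int(rng.integers(cfg.malignant_spicule_range[0], cfg.malignant_spicule_range[1] + 1))
    phase = rng.uniform(0, 2 * np.pi)
    # a couple of low harmonics make the spicules irregular
    amp2 = rng.uniform(0.0, 0.10)
    phase2 = rng.uniform(0, 2 * np.pi)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    radius = np.hypot(dr, dc)
    angle = np.arctan2(dc, dr)
    boundary = r0 * (
        1.0
        + cfg.malignant_spicule_amp * np.cos(k * angle + phase)
        + amp2 * np.cos(3 * angle + phase2)
    )
    mask = (radius <= boundary).astype(float)
    return ndimage.gaussian_filter(mask, sigma=cfg.malignant_margin_sigma)


def _support_bbox(profile: np.ndarray, threshold: float) -> BoundingBox:
    support = profile > threshold
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    return BoundingBox(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)


def generate_region(
    cls: Label,
    density: Density,
    rng: np.random.Generator,
    config: SyntheticConfig | None = None,
    region_id: str = "",
) -> MassRegion:
    """One phantom: textured background + one lesion; bbox is the tight
    box of the lesion support."""
    cfg = config or SyntheticConfig()
    shape = cfg.image_size
    img = _background(shape, density, cfg.noise_sd, rng)

    margin = max(cfg.benign_axis_range[1], cfg.malignant_radius_range[1]) * 1.6 + 10
    center = (
        rng.uniform(margin, shape[0] - margin),
        rng.uniform(margin, shape[1] - margin),
    )
    if cls == Label.BENIGN:
        profile = _benign_profile(shape, center, cfg, rng)
    else:
        profile = _malignant_profile(shape, center, cfg, rng)
    img = img + _LESION_AMP * profile

    max_value = (1 << cfg.bit_depth) - 1
    scale = max_value / 255.0  # keep 8-bit look, stretch for 16-bit mode
    pixels = np.clip(img * scale, 0, max_value)
    dtype = np.uint8 if cfg.bit_depth == 8 else np.uint16
    pixels = pixels.astype(dtype)

    bbox = _support_bbox(profile, _SUPPORT_THRESHOLD)
    return MassRegion(
        image=GrayImage(pixels, bit_depth=cfg.bit_depth),
        bbox=bbox,
        label=cls,
        density=density,
        region_id=region_id,
    )


@dataclass
class SyntheticDataset:
    """Stratified train/test split of generated regions."""

    train: list[MassRegion] = field(default_factory=list)
    test: list[MassRegion] = field(default_factory=list)

    @property
    def all_regions(self) -> list[MassRegion]:
        return self.train + self.test


def generate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """``n_per_class`` regions per class, stratified 70:30 train/test.

    Fully deterministic for a fixed ``config.seed``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    densities = list(Density)
    probs = np.asarray(cfg.density_mix, dtype=float)

    regions: list[MassRegion] = []
    for cls in (Label.BENIGN, Label.MALIGNANT):
        for i in range(cfg.n_per_class):
            density = densities[int(rng.choice(4, p=probs))]
            regions.append(
                generate_region(
                    cls, density, rng, cfg,
                    region_id=f"{cls.name.lower()}_{i:04d}",
                )
            )

    n_train = int(round(cfg.train_fraction * cfg.n_per_class))
    ds = SyntheticDataset()
    for cls in (Label.BENIGN, Label.MALIGNANT):
        members = [r for r in regions if r.label == cls]
        order = rng.permutation(len(members))
        for j, idx in enumerate(order):
            (ds.train if j < n_train else ds.test).append(members[idx])
    return ds


def summary_features(region: MassRegion) -> np.ndarray:
    """Three hand-crafted lesion descriptors: margin gradient, boundary
    roughness (spiculation), eccentricity.

    Used to audit that the generated classes are linearly separable at
    all, independently of any CNN.
    """
    crop = region.crop().astype(float)
    # lesion mask by thresholding between background and lesion levels
    thr = 0.5 * (crop.min() + crop.max())
    mask = crop >= thr
    if not mask.any():
        return np.zeros(3)

    # margin sharpness: mean gradient magnitude on the mask boundary
    gy, gx = np.gradient(crop)
    grad = np.hypot(gy, gx)
    boundary = mask ^ ndimage.binary_erosion(mask)
    margin_grad = float(grad[boundary].mean()) if boundary.any() else 0.0

    # boundary roughness: relative spread of boundary radii about centroid
    rr, cc = np.nonzero(boundary)
    if rr.size:
        cy, cx = ndimage.center_of_mass(mask)
        radii = np.hypot(rr - cy, cc - cx)
        roughness = float(radii.std() / max(radii.mean(), 1e-9))
    else:
        roughness = 0.0

    # eccentricity from second moments of the mask
    ys, xs = np.nonzero(mask)
    ys = ys - ys.mean()
    xs = xs - xs.mean()
    cov = np.cov(np.vstack([ys, xs]))
    evals = np.sort(np.linalg.eigvalsh(cov))
    ecc = float(np.sqrt(max(0.0, 1.0 - evals[0] / max(evals[1], 1e-9))))
    return np.array([margin_grad, roughness, ecc])
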