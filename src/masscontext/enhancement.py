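"""Contrast enhancement of ROIs prior to model input.

The chain is: global histogram equalization, then unsharp masking with
strength 0.8, then a 3 x 3 median filter.  It targets low-contrast
digitized-film mammograms; full-field digital images with good native
contrast are typically run with ``enabled=False`` (identity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class EnhancementConfig:
    """Parameters of the enhancement chain.

    ``strength`` is the unsharp-masking amount (fraction of the high-pass
    residual added back); ``gaussian_sigma`` the blur scale of that
    residual in pixels; ``median_kernel`` the side of the square median
    window (odd).  ``apply_after_resize`` records where in the pipeline
    the chain runs: after resizing to 224 x 224 (default; uniform kernel
    scale across masses of any size) or on the raw crop.
    """

    enabled: bool = True
    strength: float = 0.8
    median_kernel: int = 3
    gaussian_sigma: float = 1.0
    n_bins: int = 256
    apply_after_resize: bool = True

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("sharpening strength must be >= 0")
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median kernel side must be odd and positive")


def histogram_equalize(pixels: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Global histogram equalization over the array's own intensity range.

    Maps intensities through the empirical CDF so the output occupies
    ``[lo, hi]`` (the input range) near-uniformly.  A constant image maps
    to a constant image.
    """
    x = np.asarray(pixels, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return x.copy()
    hist, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    cdf = hist.cumsum().astype(float)
    cdf /= cdf[-1]
    idx = np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)
    return lo + cdf[idx] * (hi - lo)


def unsharp_mask(
    pixels: np.ndarray, strength: float = 0.8, sigma: float = 1.0
) -> np.ndarray:
    """Sharpen by adding back a scaled high-pass residual:
    ``out = x + strength * (x - gaussian(x, sigma))``."""
    x = np.asarray(pixels, dtype=float)
    blurred = ndimage.gaussian_filter(x, sigma=sigma)
    return x + strength * (x - blurred)


def median_denoise(pixels: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Square median filter (reflective boundary)."""
    return ndimage.median_filter(np.asarray(pixels, dtype=float), size=kernel)


def enhance(
    roi_pixels: np.ndarray, config: EnhancementConfig | None = None
) -> np.ndarray:
    """Run the full enhancement chain on one ROI.

    Output has the input's shape and is clipped to the input's intensity
    range; with ``enabled=False`` the input is returned unchanged (copy).
    """
    config = config or EnhancementConfig()
    x = np.asarray(roi_pixels, dtype=float)
    if x.size == 0:
        raise ValueError("empty ROI")
    if not config.enabled:
        return x.copy()
    lo, hi = x.min(), x.max()
    out = histogram_equalize(x, config.n_bins)
    out = unsharp_mask(out, config.strength, config.gaussian_sigma)
    out = median_denoise(out, config.median_kernel)
    return np.clip(out, lo, hi)
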