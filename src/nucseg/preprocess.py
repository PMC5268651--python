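"""Background correction and smoothing ahead of segmentation.

Rolling-ball background subtraction (ImageJ-style, radius in micrometres)
followed by at most one linear or non-linear filter.  An all-disabled
configuration is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import restoration, transform

from .core import CalibratedImage, um_to_px

FILTERS = ("none", "gaussian", "median", "mean", "min", "max", "variance")


@dataclass(frozen=True)
class PreprocessConfig:
    background_radius_um: float = 0.0   # 0 disables background subtraction
    filter: str = "none"
    filter_radius_um: float = 0.0

    def __post_init__(self):
        if self.background_radius_um < 0 or self.filter_radius_um < 0:
            raise ValueError("radii must be >= 0")
        if self.filter not in FILTERS:
            raise ValueError(f"unknown filter {self.filter!r}; choose from {FILTERS}")


def subtract_background(pixels: np.ndarray, radius_px: int) -> np.ndarray:
    """Rolling-ball background subtraction.

    For large radii the image is computed at a coarser scale (the background
    is smooth by construction) and the estimate is resized back, mirroring
    how ImageJ handles big structuring elements.
    """
    if radius_px <= 0:
        return pixels
    scale = max(1, radius_px // 16)
    if scale > 1:
        small = transform.rescale(pixels, 1.0 / scale, anti_aliasing=True,
                                  preserve_range=True)
        bg_small = restoration.rolling_ball(small, radius=max(1, radius_px // scale))
        bg = transform.resize(bg_small, pixels.shape, preserve_range=True)
    else:
        bg = restoration.rolling_ball(pixels, radius=radius_px)
    return np.clip(pixels - bg, 0, None)


def _apply_filter(pixels: np.ndarray, name: str, radius_px: int) -> np.ndarray:
    if name == "none" or radius_px <= 0 and name != "gaussian":
        if name == "none":
            return pixels
    size = 2 * max(1, radius_px) + 1
    if name == "gaussian":
        sigma = max(radius_px, 1) / 2.0
        return ndimage.gaussian_filter(pixels, sigma=sigma)
    if name == "median":
        return ndimage.median_filter(pixels, size=size)
    if name == "mean":
        return ndimage.uniform_filter(pixels, size=size)
    if name == "min":
        return ndimage.minimum_filter(pixels, size=size)
    if name == "max":
        return ndimage.maximum_filter(pixels, size=size)
    if name == "variance":
        mean = ndimage.uniform_filter(pixels, size=size)
        mean_sq = ndimage.uniform_filter(pixels * pixels, size=size)
        return np.clip(mean_sq - mean * mean, 0, None)
    raise ValueError(f"unknown filter {name!r}")


def preprocess(image: CalibratedImage, cfg: PreprocessConfig) -> CalibratedImage:
    """Apply background subtraction then the configured filter.

    Output has the same shape and calibration; intensities stay >= 0.
    """
    px = image.pixels
    bg_px = um_to_px(cfg.background_radius_um, image.pixel_size_um)
    if bg_px > 0:
        px = subtract_background(px, bg_px)
    if cfg.filter != "none":
        r_px = um_to_px(cfg.filter_radius_um, image.pixel_size_um)
        px = _apply_filter(px, cfg.filter, r_px)
    return image.with_pixels(np.clip(px, 0, None))
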