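"""Two-pass intensity segmentation.

Pass 1: a global auto-threshold over the whole image yields seed regions.
Seeds are then conditionally dilated -- grown by at most ``dilation_um``
(default 3 um) but confined to their Voronoi cell, so neighbouring seeds
never fuse.  Pass 2: within each dilated region an auto-threshold is
recomputed from that region's pixel population only, which recovers dim
structures (blebs) that the global threshold misses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CalibratedImage, LabelMask, NucleusContour, mask_to_contours, um_to_px
from .thresholds import DegenerateHistogramError, auto_threshold

logger = logging.getLogger("nucseg")

_STRUCT8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class TwoPassConfig:
    global_method: str = "triangle"
    local_method: str = "mean"
    dilation_um: float = 3.0
    min_seed_area_um2: float = 20.0

    def __post_init__(self):
        if self.dilation_um < 0 or self.min_seed_area_um2 < 0:
            raise ValueError("dilation_um and min_seed_area_um2 must be >= 0")


def _clean_binary(binary: np.ndarray, min_area_px: float) -> np.ndarray:
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    if n == 0:
        return np.zeros_like(binary, bool)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= min_area_px) + 1
    return np.isin(labels, keep)


def _flag_border(contours: list[NucleusContour], shape: tuple[int, int]) -> None:
    for c in contours:
        x, y = c.points[:, 0], c.points[:, 1]
        c.border = bool(x.min() <= 1 or y.min() <= 1
                        or x.max() >= shape[1] - 2 or y.max() >= shape[0] - 2)


def global_pass(image: CalibratedImage, cfg: TwoPassConfig) -> list[NucleusContour]:
    """Seed detection: global threshold, hole filling, small-object removal.

    A blank (constant) image has no threshold and yields no seeds.
    """
    try:
        thr = auto_threshold(image.pixels, cfg.global_method)
    except DegenerateHistogramError:
        return []
    min_area_px = cfg.min_seed_area_um2 / image.pixel_size_um ** 2
    binary = _clean_binary(image.pixels >= thr, min_area_px)
    labels, n = ndimage.label(binary, structure=_STRUCT8)
    contours = mask_to_contours(LabelMask(labels), stage="seed")
    _flag_border(contours, image.shape)
    logger.debug("global_pass: threshold=%.3g, %d seeds", thr, len(contours))
    return contours


def conditional_dilate(seeds: list[NucleusContour] | LabelMask,
                       image_shape: tuple[int, int],
                       dilation_um: float, pixel_size_um: float) -> LabelMask:
    """Grow each seed by <= dilation distance within its Voronoi cell.

    Voronoi assignment is nearest seed *region* (not centroid): the Euclidean
    distance transform of the seed raster supplies, for every background
    pixel, both the distance to and the identity of the closest seed pixel.
    Output regions are pairwise disjoint and each contains its seed.
    """
    if isinstance(seeds, LabelMask):
        labels = seeds.labels
    else:
        from .core import contours_to_mask
        labels = contours_to_mask(seeds, image_shape).labels
    if not labels.any():
        return LabelMask(np.zeros(image_shape, np.int32))
    dil_px = um_to_px(dilation_um, pixel_size_um)
    dist, (iy, ix) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
    nearest = labels[iy, ix]
    out = np.where(dist <= dil_px, nearest, 0).astype(np.int32)
    return LabelMask(out)


def local_threshold_pass(image: CalibratedImage, dilated: LabelMask,
                         cfg: TwoPassConfig,
                         global_threshold: float | None = None) -> list[NucleusContour]:
    """Per-seed local threshold on the dilated region's pixel population.

    Keeps the largest thresholded component per region, fills holes.  A
    degenerate (constant) region falls back to the global threshold value.
    """
    if global_threshold is None:
        global_threshold = auto_threshold(image.pixels, cfg.global_method)
    out_labels = np.zeros(image.shape, np.int32)
    objects = ndimage.find_objects(dilated.labels)
    for k in dilated.ids:
        sl = objects[k - 1]
        region = dilated.labels[sl] == k
        vals = image.pixels[sl][region]
        try:
            thr = auto_threshold(vals, cfg.local_method)
        except DegenerateHistogramError:
            thr = global_threshold
        binary = np.zeros_like(region)
        binary[region] = image.pixels[sl][region] >= thr
        labels, n = ndimage.label(binary, structure=_STRUCT8)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
        comp = ndimage.binary_fill_holes(labels == best)
        out_labels[sl][comp] = k
    contours = mask_to_contours(LabelMask(out_labels), stage="initial")
    _flag_border(contours, image.shape)
    return contours


def segment_twopass(image: CalibratedImage, cfg: TwoPassConfig
                    ) -> tuple[list[NucleusContour], LabelMask]:
    """Full two-pass segmentation: seeds -> conditional dilation -> local pass.

    Returns the initial contours and the dilated-region mask (needed by the
    refinement stage to bound each nucleus).
    """
    seeds = global_pass(image, cfg)
    if not seeds:
        return [], LabelMask(np.zeros(image.shape, np.int32))
    from .core import contours_to_mask
    seed_mask = contours_to_mask(seeds, image.shape)
    dilated = conditional_dilate(seed_mask, image.shape, cfg.dilation_um,
                                 image.pixel_size_um)
    thr = auto_threshold(image.pixels, cfg.global_method)
    initial = local_threshold_pass(image, dilated, cfg, global_threshold=thr)
    return initial, dilated
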