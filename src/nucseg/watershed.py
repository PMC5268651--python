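"""Conditional watershed: split touching nuclei, protect blebs.

A distance-transform watershed proposes separation lines inside each
refined ROI.  A proposed split is accepted only if (a) both fragments meet
the minimum-area criterion and (b) the intensity decays enough across the
line: the median perpendicular intensity profile over a 3 um wide
subregion must have a min/max ratio at or below the user cut-off (default
0.75).  Vetoed splits are merged back, so the crevice-bound neck of a bleb
-- which shows no background-level intensity valley -- stays attached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed as _skimage_watershed

from .core import CalibratedImage, LabelMask, NucleusContour, contours_to_mask, \
    mask_to_contours, um_to_px

logger = logging.getLogger("nucseg")

_STRUCT8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class WatershedConfig:
    min_area_um2: float = 10.0
    decay_cutoff: float = 0.75
    profile_halfwidth_um: float = 1.5    # 3 um subregion across the line

    def __post_init__(self):
        if not (0 < self.decay_cutoff < 1):
            raise ValueError("decay_cutoff must be in (0, 1)")
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be > 0")


def watershed_candidates(roi_mask: np.ndarray
                         ) -> tuple[LabelMask, dict[tuple[int, int], np.ndarray]]:
    """Distance-transform watershed of one binary ROI.

    The distance transform is smoothed (Gaussian sigma = 1 px) to suppress
    spurious maxima before seeding.  Returns the fragment label mask and,
    per adjacent fragment pair, the ordered (x, y) pixel chain of their
    separation line.  A single-fragment result has no lines.
    """
    roi_mask = np.asarray(roi_mask).astype(bool)
    dist = ndimage.distance_transform_edt(roi_mask)
    smooth = ndimage.gaussian_filter(dist, sigma=1.0)
    peaks = peak_local_max(smooth, labels=roi_mask, min_distance=3,
                           exclude_border=False)
    markers = np.zeros(roi_mask.shape, np.int32)
    for idx, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = idx
    n_markers = len(peaks)
    if n_markers <= 1:
        frag = LabelMask(roi_mask.astype(np.int32))
        return frag, {}
    labels = _skimage_watershed(-smooth, markers, mask=roi_mask,
                                watershed_line=True)
    line_px = roi_mask & (labels == 0)
    # assign line pixels to their fragment pair and re-grow them into fragments
    lines: dict[tuple[int, int], list[tuple[int, int]]] = {}
    ys, xs = np.nonzero(line_px)
    for y, x in zip(ys, xs):
        neigh = labels[max(0, y - 1):y + 2, max(0, x - 1):x + 2]
        vals = sorted(set(neigh.ravel()) - {0})
        if len(vals) >= 2:
            key = (int(vals[0]), int(vals[1]))
            lines.setdefault(key, []).append((x, y))
    # fold line pixels back into the nearest fragment so area is conserved
    filled = _skimage_watershed(-smooth, markers, mask=roi_mask)
    ordered = {k: _order_chain(np.array(v, float)) for k, v in lines.items()
               if len(v) >= 2}
    return LabelMask(filled), ordered


def _order_chain(points: np.ndarray) -> np.ndarray:
    """Order an unordered set of line pixels into a chain (greedy nearest)."""
    pts = points.copy()
    # start from an endpoint: the point farthest from the centroid
    start = int(np.argmax(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    order = [start]
    used = {start}
    for _ in range(len(pts) - 1):
        cur = pts[order[-1]]
        d = np.linalg.norm(pts - cur, axis=1)
        d[list(used)] = np.inf
        nxt = int(np.argmin(d))
        order.append(nxt)
        used.add(nxt)
    return pts[order]


def median_decay_ratio(image: CalibratedImage, line: np.ndarray,
                       cfg: WatershedConfig = WatershedConfig()) -> float:
    """Min/max ratio of the median perpendicular intensity profile.

    For every line pixel the intensity is sampled along the local
    perpendicular across 2 x ``profile_halfwidth_um``; the per-offset
    median over all line pixels forms the median profile.  1.0 means no
    decay (featureless); small values mean a deep valley.
    """
    line = np.asarray(line, dtype=float)
    if len(line) < 2:
        raise ValueError("separation line needs >= 2 pixels")
    half_px = um_to_px(cfg.profile_halfwidth_um, image.pixel_size_um)
    offsets = np.arange(-half_px, half_px + 0.5, 0.5)
    profiles = []
    n = len(line)
    for idx in range(n):
        lo, hi = max(0, idx - 2), min(n, idx + 3)   # 5-pixel direction window
        seg = line[hi - 1] - line[lo]
        norm = np.hypot(*seg)
        if norm == 0:
            continue
        t = seg / norm
        perp = np.array([-t[1], t[0]])
        px = line[idx, 0] + offsets * perp[0]
        py = line[idx, 1] + offsets * perp[1]
        vals = ndimage.map_coordinates(image.pixels, [py, px], order=1,
                                       mode="nearest")
        profiles.append(vals)
    median = np.median(np.array(profiles), axis=0)
    mx = float(median.max())
    if mx <= 0:
        return 1.0
    return float(median.min()) / mx


def conditional_split(image: CalibratedImage, roi: NucleusContour,
                      cfg: WatershedConfig = WatershedConfig(),
                      refine_cfg=None) -> list[NucleusContour]:
    """Split one refined ROI where both size and intensity-decay criteria pass.

    Separation lines are evaluated in ascending decay-ratio order; a line is
    accepted only if both resulting fragments stay above ``min_area_um2``
    and the ratio is <= ``decay_cutoff`` (a ratio strictly above the cut-off
    means insufficient decay, so the parts are merged back).  Newly split
    contours are re-refined when ``refine_cfg`` is given.
    """
    mask = contours_to_mask([roi], image.shape)
    binary = mask.labels > 0
    frag, lines = watershed_candidates(binary)
    min_area_px = cfg.min_area_um2 / image.pixel_size_um ** 2
    labels = frag.labels.copy()
    if lines:
        ratios = {pair: median_decay_ratio(image, chain, cfg)
                  for pair, chain in lines.items()}
        merged = _merge_map(labels)
        for pair in sorted(ratios, key=ratios.get):
            a, b = (_find(merged, pair[0]), _find(merged, pair[1]))
            if a == b:
                continue
            area_a = int(np.sum(labels == a))
            area_b = int(np.sum(labels == b))
            veto = (min(area_a, area_b) < min_area_px
                    or ratios[pair] > cfg.decay_cutoff)
            if veto:
                keep, drop = (a, b) if area_a >= area_b else (b, a)
                labels[labels == drop] = keep
                merged[drop] = keep
        # relabel sequentially
    out_ids = [v for v in np.unique(labels) if v > 0]
    relabeled = np.zeros_like(labels)
    for new_id, old in enumerate(out_ids, start=1):
        relabeled[labels == old] = new_id
    contours = mask_to_contours(LabelMask(relabeled), stage="refined")
    for i, c in enumerate(contours):
        c.nucleus_id = roi.nucleus_id if len(contours) == 1 else -1  # re-id upstream
        c.border = roi.border
    if refine_cfg is not None and len(contours) > 1:
        from .refine import refine
        contours = [refine(image, c, refine_cfg)[0] for c in contours]
    return contours


def _merge_map(labels: np.ndarray) -> dict[int, int]:
    return {int(v): int(v) for v in np.unique(labels) if v > 0}


def _find(merged: dict[int, int], k: int) -> int:
    while merged.get(k, k) != k:
        k = merged[k]
    return k
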