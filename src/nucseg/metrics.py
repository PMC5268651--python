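"""Segmentation quality metrics against multi-observer ground truth.

Two per-nucleus error metrics compare an automatic contour C with each
observer's manual contour GT_k:

* AHD (average Hausdorff distance, um): mean over contour points of the
  minimum Euclidean distance to the other contour, symmetrized by taking
  the max of the two directions, averaged over observers.
* NSI (non-similarity index): non-overlapping area over the summed areas,
  (A_C + A_GT - 2 * A_intersection) / (A_C + A_GT); 0 for identical
  regions, 1 for disjoint ones.

Both are scaled by a positive control -- the mean pairwise value between
the observers themselves -- and averaged into one integrated error; a
value below 1 means the automatic contour is closer to the observers than
the observers are to each other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .core import GroundTruthSet, NucleusContour, _rasterize

logger = logging.getLogger("nucseg")


@dataclass
class ValidationRecord:
    nucleus_id: int
    ahd_raw: float        # um
    nsi_raw: float
    ahd_pc: float
    nsi_pc: float
    ahd_scaled: float
    nsi_scaled: float
    error: float
    degenerate_pc: bool = False


def directed_avg_distance(A: NucleusContour, B: NucleusContour,
                          pixel_size_um: float = 1.0) -> float:
    """h(A, B): mean over A's points of the min distance to B's points, in um.

    Both contours are densely resampled (<= 0.5 px spacing) first so vertex
    density does not bias the average.
    """
    a = A.resample(0.5)
    b = B.resample(0.5)
    d, _ = cKDTree(b).query(a)
    return float(d.mean()) * pixel_size_um


def ahd(C: NucleusContour, gts: list[NucleusContour],
        pixel_size_um: float = 1.0) -> float:
    """Mean over observers of max[h(C, GT_k), h(GT_k, C)]."""
    if not gts:
        raise ValueError(f"no ground truth matched to nucleus {C.nucleus_id}")
    vals = [max(directed_avg_distance(C, g, pixel_size_um),
                directed_avg_distance(g, C, pixel_size_um)) for g in gts]
    return float(np.mean(vals))


def _mask_pair(A: NucleusContour, B: NucleusContour) -> tuple[np.ndarray, np.ndarray]:
    pts = np.vstack([A.points, B.points])
    x1 = int(np.ceil(pts[:, 0].max())) + 2
    y1 = int(np.ceil(pts[:, 1].max())) + 2
    shape = (max(y1, 1), max(x1, 1))
    return _rasterize(A.points, shape), _rasterize(B.points, shape)


def nsi_pair(A: NucleusContour, B: NucleusContour) -> float:
    """Non-similarity of one contour pair, computed on rasterized masks."""
    ma, mb = _mask_pair(A, B)
    area_a, area_b = int(ma.sum()), int(mb.sum())
    inter = int((ma & mb).sum())
    total = area_a + area_b
    if total == 0:
        raise ValueError("zero total area")
    return (total - 2 * inter) / total


def nsi(C: NucleusContour, gts: list[NucleusContour]) -> float:
    """Mean over observers of the pairwise non-similarity index."""
    if not gts:
        raise ValueError(f"no ground truth matched to nucleus {C.nucleus_id}")
    return float(np.mean([nsi_pair(C, g) for g in gts]))


def positive_control(gt: GroundTruthSet, nucleus_id: int,
                     pixel_size_um: float = 1.0) -> tuple[float, float]:
    """Inter-observer AHD and NSI: mean over unordered observer pairs.

    The symmetric terms of the ordered-pair sum make this equal to the mean
    over the K*(K-1)/2 unordered pairs.
    """
    obs = gt.observers
    if len(obs) < 2:
        raise ValueError("need >= 2 observers")
    ahd_vals, nsi_vals = [], []
    for k, l in combinations(obs, 2):
        a = gt.contour(k, nucleus_id)
        b = gt.contour(l, nucleus_id)
        ahd_vals.append(max(directed_avg_distance(a, b, pixel_size_um),
                            directed_avg_distance(b, a, pixel_size_um)))
        nsi_vals.append(nsi_pair(a, b))
    return float(np.mean(ahd_vals)), float(np.mean(nsi_vals))


def scale_and_error(nucleus_id: int, raw: tuple[float, float],
                    pc: tuple[float, float]) -> ValidationRecord:
    """Scale raw (AHD, NSI) by the positive control and integrate.

    error = (AHD_scaled + NSI_scaled) / 2; a degenerate (zero) positive
    control flags the record for exclusion from summaries.
    """
    ahd_raw, nsi_raw = raw
    ahd_pc, nsi_pc = pc
    if ahd_pc <= 0 or nsi_pc <= 0:
        return ValidationRecord(nucleus_id, ahd_raw, nsi_raw, ahd_pc, nsi_pc,
                                np.nan, np.nan, np.nan, degenerate_pc=True)
    ahd_s = ahd_raw / ahd_pc
    nsi_s = nsi_raw / nsi_pc
    return ValidationRecord(nucleus_id, ahd_raw, nsi_raw, ahd_pc, nsi_pc,
                            ahd_s, nsi_s, 0.5 * (ahd_s + nsi_s))


def match_contours(pred: list[NucleusContour], ref: list[NucleusContour],
                   shape: tuple[int, int]) -> dict[int, int]:
    """Correspondence pred.nucleus_id -> ref.nucleus_id by maximal mask overlap.

    Hungarian assignment on the pairwise overlap matrix; pairs with zero
    overlap are dropped (unmatched contours are reported, not scored).
    """
    if not pred or not ref:
        return {}
    masks_p = [_rasterize(c.points, shape) for c in pred]
    masks_r = [_rasterize(c.points, shape) for c in ref]
    overlap = np.zeros((len(pred), len(ref)))
    for i, mp in enumerate(masks_p):
        for j, mr in enumerate(masks_r):
            overlap[i, j] = np.sum(mp & mr)
    rows, cols = linear_sum_assignment(-overlap)
    out = {}
    for i, j in zip(rows, cols):
        if overlap[i, j] > 0:
            out[pred[i].nucleus_id] = ref[j].nucleus_id
        else:
            logger.info("unmatched predicted nucleus %d", pred[i].nucleus_id)
    return out


def validate(pred: list[NucleusContour], gt: GroundTruthSet,
             shape: tuple[int, int], pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Per-nucleus validation records for a predicted contour set.

    Predicted contours are matched to ground-truth nuclei by mask overlap
    against the first observer; each matched nucleus gets AHD/NSI raw,
    positive-control, scaled values and the integrated error.
    """
    first_obs = gt.observers[0]
    ref = list(gt.contours_by_observer[first_obs])
    matches = match_contours(pred, ref, shape)
    records = []
    for c in pred:
        if c.nucleus_id not in matches:
            continue
        nid = matches[c.nucleus_id]
        gts = [gt.contour(k, nid) for k in gt.observers]
        raw = (ahd(c, gts, pixel_size_um), nsi(c, gts))
        pc = positive_control(gt, nid, pixel_size_um)
        rec = scale_and_error(nid, raw, pc)
        records.append(rec.__dict__)
    return pd.DataFrame(records)
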