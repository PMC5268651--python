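"""Morpho-textural feature extraction from segmented nuclei.

Shape: area, perimeter, fitted-ellipse axes, aspect ratio, circularity,
solidity (in um units); total absolute boundary curvature; normalized
elliptic Fourier descriptor (EFD) amplitudes whose sum over harmonics >= 2
scores deviation from an ellipse (size / rotation / starting-point
invariant, after Kuhl & Giardina).  Texture: gray-level co-occurrence
matrix attributes (ASM, contrast, correlation, homogeneity, entropy)
averaged over the 0/45/90/135 degree directions for rotation invariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from .core import CalibratedImage, NucleusContour, _rasterize, polygon_area, \
    polygon_perimeter, resample_closed

logger = logging.getLogger("nucseg")

GLCM_NAMES = ("asm", "contrast", "correlation", "idm", "entropy")


@dataclass(frozen=True)
class FeatureConfig:
    n_harmonics: int = 20
    curvature_step_um: float = 0.5
    glcm_levels: int = 64
    glcm_distance_px: int = 1
    include_border: bool = False


def shape_features(contour: NucleusContour, pixel_size: float) -> dict[str, float]:
    """Standard shape attributes, converted to micrometre units.

    Area by the shoelace formula, perimeter as polygon length, ellipse from
    the second-order central moments of the rasterized region, circularity
    4*pi*A/P^2, solidity A / A_convex_hull.
    """
    pts = contour.points
    area_px = abs(polygon_area(pts))
    perim_px = polygon_perimeter(pts)
    if area_px <= 0 or perim_px <= 0:
        raise ValueError("degenerate polygon")
    # moments-based ellipse on the rasterized region
    shift = pts - pts.min(axis=0) + 2
    shape = (int(np.ceil(shift[:, 1].max())) + 3, int(np.ceil(shift[:, 0].max())) + 3)
    mask = _rasterize(shift, shape)
    props = regionprops(mask.astype(np.uint8))[0]
    major_px = props.axis_major_length
    minor_px = props.axis_minor_length
    hull = ShapelyPolygon(pts).convex_hull.area
    s = pixel_size
    return {
        "area_um2": area_px * s * s,
        "perimeter_um": perim_px * s,
        "ellipse_major_um": major_px * s,
        "ellipse_minor_um": minor_px * s,
        "aspect_ratio": major_px / max(minor_px, 1e-12),
        "circularity": min(4 * np.pi * area_px / perim_px ** 2, 1.0),
        "solidity": min(area_px / max(hull, 1e-12), 1.0),
    }


def total_curvature(contour: NucleusContour, pixel_size: float,
                    step_um: float = 0.5) -> float:
    """Sum of absolute boundary turning angles (radians).

    The contour is resampled at ``step_um`` arc spacing; segment
    orientations are differenced with wrap-around into (-pi, pi] and their
    absolute values summed.  Any convex closed contour gives 2*pi; blebs
    and crevices add extra turning.
    """
    step_px = step_um / pixel_size
    perim = contour.perimeter_px()
    if perim < 4 * step_px:
        raise ValueError("contour too short for curvature step")
    n = max(8, int(round(perim / step_px)))
    pts = resample_closed(contour.points, n=n)
    seg = np.roll(pts, -1, axis=0) - pts
    theta = np.arctan2(seg[:, 1], seg[:, 0])
    dtheta = np.diff(np.concatenate([theta, theta[:1]]))
    dtheta = (dtheta + np.pi) % (2 * np.pi) - np.pi
    return float(np.sum(np.abs(dtheta)))


# ---------------------------------------------------------------------------
# elliptic Fourier descriptors (Kuhl & Giardina)
# ---------------------------------------------------------------------------

def _efd_coefficients(pts: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Raw EFD coefficients (a_n, b_n, c_n, d_n) of a closed polygon chain."""
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    keep = dt > 1e-12
    d, dt = d[keep], dt[keep]
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    phi = 2 * np.pi * t / T
    coeffs = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        const = T / (2 * n * n * np.pi * np.pi)
        cos_d = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
        sin_d = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
        coeffs[n - 1] = const * np.array([
            np.sum(d[:, 0] / dt * cos_d),
            np.sum(d[:, 0] / dt * sin_d),
            np.sum(d[:, 1] / dt * cos_d),
            np.sum(d[:, 1] / dt * sin_d),
        ])
    return coeffs


def _normalize_efd(coeffs: np.ndarray) -> np.ndarray:
    """Normalize for starting point, rotation and size (first harmonic)."""
    a1, b1, c1, d1 = coeffs[0]
    # starting-point phase
    theta = 0.5 * np.arctan2(2 * (a1 * b1 + c1 * d1),
                             a1 * a1 + c1 * c1 - b1 * b1 - d1 * d1)
    out = coeffs.copy()
    for n in range(len(coeffs)):
        a, b, c, d = out[n]
        m = np.array([[a, b], [c, d]]) @ np.array(
            [[np.cos((n + 1) * theta), -np.sin((n + 1) * theta)],
             [np.sin((n + 1) * theta), np.cos((n + 1) * theta)]])
        out[n] = m.ravel()
    # rotation by the first semi-major axis orientation
    a1, b1, c1, d1 = out[0]
    psi = np.arctan2(c1, a1)
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    for n in range(len(out)):
        a, b, c, d = out[n]
        out[n] = (rot @ np.array([[a, b], [c, d]])).ravel()
    # scale by the first-harmonic semi-major axis
    scale = abs(out[0, 0])
    if scale > 0:
        out /= scale
    return out


def efd_features(contour: NucleusContour, n_harmonics: int = 20
                 ) -> tuple[np.ndarray, float]:
    """Normalized per-harmonic EFD amplitudes and their sum over n >= 2.

    amplitude_n = sqrt(a_n^2 + b_n^2) + sqrt(c_n^2 + d_n^2) after
    normalization; the first harmonic is the normalization ellipse, so an
    exact ellipse scores ~0.
    """
    pts = resample_closed(contour.points, n=max(24 * n_harmonics, 360))
    coeffs = _normalize_efd(_efd_coefficients(pts, n_harmonics))
    amps = np.hypot(coeffs[:, 0], coeffs[:, 1]) + np.hypot(coeffs[:, 2], coeffs[:, 3])
    return amps, float(np.sum(amps[1:]))


# ---------------------------------------------------------------------------
# GLCM texture
# ---------------------------------------------------------------------------

def glcm_features(image: CalibratedImage | np.ndarray, mask: np.ndarray,
                  levels: int = 64, distance_px: int = 1) -> dict[str, float]:
    """Angle-averaged co-occurrence features of the in-mask intensities.

    Intensities are quantized to ``levels`` gray levels over the in-mask
    min-max range; symmetric normalized co-occurrence matrices at 0, 45,
    90, 135 degrees; pairs touching the outside of the mask are excluded.
    A constant patch returns entropy 0, ASM 1, contrast 0.
    """
    px = image.pixels if isinstance(image, CalibratedImage) else np.asarray(image)
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 64:
        raise ValueError("mask too small for texture features")
    vals = px[mask]
    lo, hi = float(vals.min()), float(vals.max())
    quant = np.zeros(px.shape, dtype=np.uint8)       # 0 = outside mask
    if hi > lo:
        q = np.floor((px - lo) / (hi - lo) * levels).astype(int)
        quant[mask] = np.clip(q[mask], 0, levels - 1) + 1
    else:
        quant[mask] = 1
    angles = [0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    glcm = graycomatrix(quant, distances=[distance_px], angles=angles,
                        levels=levels + 1, symmetric=True, normed=False)
    glcm = glcm[1:, 1:, :, :].astype(float)          # drop outside-mask pairs
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    sums[sums == 0] = 1.0
    glcm /= sums
    feats = {k: 0.0 for k in GLCM_NAMES}
    for prop, key in (("ASM", "asm"), ("contrast", "contrast"),
                      ("correlation", "correlation"), ("homogeneity", "idm")):
        v = graycoprops(glcm, prop)[0]
        feats[key] = float(np.mean(v))
    ent = []
    for a in range(len(angles)):
        p = glcm[:, :, 0, a]
        nz = p[p > 0]
        ent.append(-np.sum(nz * np.log2(nz)))
    feats["entropy"] = float(np.mean(ent))
    return feats


def extract_features(image: CalibratedImage, contour: NucleusContour,
                     cfg: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """Complete feature vector for one nucleus."""
    out = {"nucleus_id": contour.nucleus_id, "border": int(contour.border)}
    out.update(shape_features(contour, image.pixel_size_um))
    out["total_curvature_rad"] = total_curvature(
        contour, image.pixel_size_um, cfg.curvature_step_um)
    amps, efd_sum = efd_features(contour, cfg.n_harmonics)
    for n in range(1, cfg.n_harmonics + 1):
        out[f"efd_{n}"] = float(amps[n - 1])
    out["efd_sum"] = efd_sum
    mask = _rasterize(contour.points, image.shape)
    tex = glcm_features(image, mask, cfg.glcm_levels, cfg.glcm_distance_px)
    out.update({f"glcm_{k}": v for k, v in tex.items()})
    return out


def extract_all(image: CalibratedImage, contours: list[NucleusContour],
                cfg: FeatureConfig = FeatureConfig(),
                labels: dict[int, str] | None = None) -> pd.DataFrame:
    """One feature row per nucleus; border-flagged nuclei excluded by default."""
    rows = []
    for c in contours:
        if c.border and not cfg.include_border:
            logger.info("nucleus %d touches the border; excluded", c.nucleus_id)
            continue
        row = extract_features(image, c, cfg)
        if labels is not None:
            row["class"] = labels.get(c.nucleus_id, "")
        rows.append(row)
    return pd.DataFrame(rows)
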