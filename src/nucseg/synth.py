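"""Synthetic fluorescence fields of nuclei with known ground truth.

Emulates the phenotypes the segmentation pipeline must handle: ovoid
nuclei, low-intensity blebs attached through crevices, touching nucleus
pairs with a parametric intensity valley, intranuclear bright spots
(chromocenters), linear intensity gradients (chromatin ruffling), uneven
illumination and Poisson/Gaussian noise.  Every nucleus carries a
ground-truth mask (bleb pixels belong to their parent nucleus) and a class
label (normal / dysmorphic).

Shapes are rendered from analytic quasi-signed-distance fields with a
sub-pixel soft edge, so geometry is resolution-consistent; all randomness
flows from explicit seeds stored in the specs -- rendering a spec twice is
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon as ShapelyPolygon

from .core import CalibratedImage, GroundTruthSet, LabelMask, NucleusContour, \
    mask_to_contours, resample_closed

DEFAULT_PIXEL_SIZE_UM = 0.2
DEFAULT_BACKGROUND = 10.0
DEFAULT_BODY_INTENSITY = 180.0
DEFAULT_GAUSSIAN_SD = 3.0


@dataclass(frozen=True)
class BlebSpec:
    neck_angle: float              # rad, position on the body boundary
    neck_width_um: float
    bleb_radius_um: float
    intensity_fraction: float = 0.5     # <= 1: blebs are dimmer than the body
    crevice_depth: float = 0.5          # intensity dip at the body/bleb junction

    def __post_init__(self):
        if not (0 < self.intensity_fraction <= 1):
            raise ValueError("intensity_fraction must be in (0, 1]")
        if self.neck_width_um >= 2 * self.bleb_radius_um:
            raise ValueError("neck wider than the bleb diameter")


@dataclass(frozen=True)
class NucleusSpec:
    center_um: tuple[float, float]
    semi_axes_um: tuple[float, float]
    orientation_rad: float = 0.0
    body_intensity: float = DEFAULT_BODY_INTENSITY
    blebs: tuple[BlebSpec, ...] = ()
    ruffling_gradient: float = 0.0      # fraction of intensity span across the body
    chromocenters: tuple[tuple[float, float, float, float], ...] = ()
    #                    (dx_um, dy_um, radius_um, boost_fraction), body frame
    roughness: tuple[tuple[int, float, float], ...] = ()
    #                    (harmonic, amplitude_um, phase)
    class_label: str = "normal"

    def max_extent_um(self) -> float:
        ext = max(self.semi_axes_um)
        for b in self.blebs:
            ext = max(ext, self._bleb_reach(b))
        return ext + sum(a for _, a, _ in self.roughness)

    def _bleb_reach(self, b: BlebSpec) -> float:
        h = np.sqrt(max(b.bleb_radius_um ** 2 - (b.neck_width_um / 2) ** 2, 0))
        return max(self.semi_axes_um) + h + b.bleb_radius_um

    def bleb_center_um(self, b: BlebSpec) -> tuple[float, float]:
        """Bleb circle center: on the boundary normal, offset so the chord
        through the body edge has the requested neck width."""
        a, bb = self.semi_axes_um
        t = b.neck_angle
        # boundary point and outward normal of the (unrotated) ellipse
        px, py = a * np.cos(t), bb * np.sin(t)
        nx, ny = bb * np.cos(t), a * np.sin(t)
        nn = np.hypot(nx, ny)
        nx, ny = nx / nn, ny / nn
        h = np.sqrt(max(b.bleb_radius_um ** 2 - (b.neck_width_um / 2) ** 2, 0))
        cx, cy = px + h * nx, py + h * ny
        co, so = np.cos(self.orientation_rad), np.sin(self.orientation_rad)
        gx = self.center_um[0] + co * cx - so * cy
        gy = self.center_um[1] + so * cx + co * cy
        return gx, gy


@dataclass(frozen=True)
class TouchingPair:
    index_a: int
    index_b: int
    valley_ratio: float

    def __post_init__(self):
        if not (0 < self.valley_ratio <= 1):
            raise ValueError("valley_ratio must be in (0, 1]")


@dataclass(frozen=True)
class FieldSpec:
    shape_px: tuple[int, int]          # (rows, cols)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    nuclei: tuple[NucleusSpec, ...] = ()
    touching_pairs: tuple[TouchingPair, ...] = ()
    illumination_gradient: float = 0.0   # fractional planar ramp corner to corner
    background: float = DEFAULT_BACKGROUND
    blur_sigma_um: float = 0.25          # optical blur of the scene
    gaussian_sd: float = DEFAULT_GAUSSIAN_SD
    poisson: bool = True
    seed: int = 0


def _quasi_sdf(spec: NucleusSpec, X: np.ndarray, Y: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """Approximate signed distance (um, positive inside) of body and blebs.

    Returns (d_union, d_body, [d_bleb...]) on the supplied um-coordinate grid.
    """
    a, b = spec.semi_axes_um
    co, so = np.cos(spec.orientation_rad), np.sin(spec.orientation_rad)
    dx = X - spec.center_um[0]
    dy = Y - spec.center_um[1]
    xl = co * dx + so * dy
    yl = -so * dx + co * dy
    rho = np.sqrt((xl / a) ** 2 + (yl / b) ** 2)
    d_body = (1.0 - rho) * min(a, b)
    if spec.roughness:
        theta = np.arctan2(yl / b, xl / a)
        m = np.zeros_like(d_body)
        for k, amp, phase in spec.roughness:
            m += amp * np.cos(k * theta + phase)
        d_body = d_body + m
    d_union = d_body.copy()
    d_blebs = []
    for bl in spec.blebs:
        cx, cy = spec.bleb_center_um(bl)
        d_bl = bl.bleb_radius_um - np.hypot(X - cx, Y - cy)
        d_blebs.append(d_bl)
        d_union = np.maximum(d_union, d_bl)
    return d_union, d_body, d_blebs


def _soft(d_um: np.ndarray, width_um: float) -> np.ndarray:
    """Smoothstep edge profile: 0 outside, 1 inside, ramp of ~width."""
    t = np.clip(d_um / width_um * 0.5 + 0.5, 0.0, 1.0)
    return t * t * (3 - 2 * t)


def render_field(spec: FieldSpec) -> tuple[CalibratedImage, LabelMask, pd.DataFrame]:
    """Render a field: calibrated image, per-nucleus ground-truth mask, labels.

    Deterministic given the spec (noise uses ``spec.seed``).  Undeclared
    overlap between nuclei raises.
    """
    h, w = spec.shape_px
    ps = spec.pixel_size_um
    declared = {frozenset((p.index_a, p.index_b)) for p in spec.touching_pairs}
    for i in range(len(spec.nuclei)):
        for j in range(i + 1, len(spec.nuclei)):
            if frozenset((i, j)) in declared:
                continue
            ci, cj = spec.nuclei[i], spec.nuclei[j]
            dist = np.hypot(ci.center_um[0] - cj.center_um[0],
                            ci.center_um[1] - cj.center_um[1])
            if dist < ci.max_extent_um() + cj.max_extent_um():
                # conservative bound; fall back to exact mask check later
                pass
    img = np.full((h, w), float(spec.background))
    if spec.illumination_gradient:
        xs = np.linspace(0, 1, w)[None, :]
        ys = np.linspace(0, 1, h)[:, None]
        img *= 1.0 + spec.illumination_gradient * (0.5 * xs + 0.5 * ys - 0.5)
    bg_plane = img.copy()
    labels = np.zeros((h, w), np.int32)
    dbest = np.full((h, w), -np.inf)
    aa = 0.6 * ps
    sdf_cache = {}
    for idx, nuc in enumerate(spec.nuclei, start=1):
        ext_px = int(np.ceil((nuc.max_extent_um() + 1.5) / ps))
        cx, cy = nuc.center_um[0] / ps, nuc.center_um[1] / ps
        x0, x1 = max(0, int(cx) - ext_px), min(w, int(cx) + ext_px + 1)
        y0, y1 = max(0, int(cy) - ext_px), min(h, int(cy) + ext_px + 1)
        X, Y = np.meshgrid(np.arange(x0, x1) * ps, np.arange(y0, y1) * ps)
        d_union, d_body, d_blebs = _quasi_sdf(nuc, X, Y)
        sdf_cache[idx] = (slice(y0, y1), slice(x0, x1), d_union)
        inside = _soft(d_union, aa)
        frac = np.where(d_body >= -aa, 1.0, 0.0)
        for bl, d_bl in zip(nuc.blebs, d_blebs):
            bleb_only = (d_bl >= -aa) & (d_body < 0)
            frac = np.where(bleb_only, np.maximum(frac, bl.intensity_fraction), frac)
        intensity = nuc.body_intensity * np.maximum(frac, 0.0)
        if nuc.ruffling_gradient:
            co, so = np.cos(nuc.orientation_rad), np.sin(nuc.orientation_rad)
            xl = co * (X - nuc.center_um[0]) + so * (Y - nuc.center_um[1])
            intensity *= np.clip(
                1.0 + nuc.ruffling_gradient * xl / nuc.semi_axes_um[0], 0.1, None)
        for bl, d_bl in zip(nuc.blebs, d_blebs):
            if bl.crevice_depth > 0:
                zone = (d_bl >= -0.3) & (np.abs(d_body) <= 0.75)
                dip = 1.0 - bl.crevice_depth * np.exp(-(d_body / 0.3) ** 2)
                intensity = np.where(zone, intensity * dip, intensity)
        for (dxc, dyc, rad, boost) in nuc.chromocenters:
            gx = nuc.center_um[0] + dxc
            gy = nuc.center_um[1] + dyc
            bump = boost * nuc.body_intensity * np.exp(
                -((X - gx) ** 2 + (Y - gy) ** 2) / (2 * (rad / 1.5) ** 2))
            intensity += np.where(d_body >= 0, bump, 0.0)
        patch = bg_plane[y0:y1, x0:x1] + inside * intensity
        img[y0:y1, x0:x1] = np.maximum(img[y0:y1, x0:x1], patch)
        gt_inside = d_union >= 0
        clash = gt_inside & (dbest[y0:y1, x0:x1] > 0)
        if clash.any():
            others = set(labels[y0:y1, x0:x1][clash].tolist())
            if not all(frozenset((idx - 1, o - 1)) in declared for o in others):
                raise ValueError(f"undeclared overlap between nuclei "
                                 f"{sorted(o - 1 for o in others)} and {idx - 1}")
        update = gt_inside & (d_union > dbest[y0:y1, x0:x1])
        sub = labels[y0:y1, x0:x1]
        sub[update] = idx
        db = dbest[y0:y1, x0:x1]
        db[update] = d_union[update]
        dbest[y0:y1, x0:x1] = np.where(gt_inside, np.maximum(db, d_union), db)
    # intensity valley between declared touching nuclei
    for pair in spec.touching_pairs:
        ia, ib = pair.index_a + 1, pair.index_b + 1
        sy_a, sx_a, da = sdf_cache[ia]
        sy_b, sx_b, db_ = sdf_cache[ib]
        y0 = min(sy_a.start, sy_b.start); y1 = max(sy_a.stop, sy_b.stop)
        x0 = min(sx_a.start, sx_b.start); x1 = max(sx_a.stop, sx_b.stop)
        X, Y = np.meshgrid(np.arange(x0, x1) * ps, np.arange(y0, y1) * ps)
        dA = _quasi_sdf(spec.nuclei[pair.index_a], X, Y)[0]
        dB = _quasi_sdf(spec.nuclei[pair.index_b], X, Y)[0]
        inside_union = (dA >= -0.3) | (dB >= -0.3)
        delta = 0.5 * (dA - dB)
        # pre-compensate the dip depth for the optical blur applied below so
        # the post-blur median-profile min/max ratio matches valley_ratio
        s = 0.4 / np.sqrt(2.0)
        atten = s / np.sqrt(s * s + spec.blur_sigma_um ** 2)
        depth = min((1.0 - pair.valley_ratio) / atten, 0.98)
        factor = 1.0 - depth * np.exp(-(delta / 0.4) ** 2)
        region = img[y0:y1, x0:x1]
        bgp = bg_plane[y0:y1, x0:x1]
        img[y0:y1, x0:x1] = np.where(inside_union,
                                     bgp + (region - bgp) * factor, region)
    if spec.blur_sigma_um > 0:
        from scipy import ndimage as _ndi
        img = _ndi.gaussian_filter(img, sigma=spec.blur_sigma_um / ps)
    rng = np.random.default_rng(spec.seed)
    if spec.poisson:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if spec.gaussian_sd > 0:
        img = img + rng.normal(0, spec.gaussian_sd, img.shape)
    img = np.clip(img, 0, None)
    table = pd.DataFrame({
        "nucleus_id": np.arange(1, len(spec.nuclei) + 1),
        "class": [n.class_label for n in spec.nuclei],
        "n_blebs": [len(n.blebs) for n in spec.nuclei],
    })
    return (CalibratedImage(pixels=img, pixel_size_um=ps),
            LabelMask(labels), table)


# ---------------------------------------------------------------------------
# spec builders (all randomness from explicit seeds)
# ---------------------------------------------------------------------------

def _random_nucleus(rng: np.random.Generator, center_um, dysmorphic: bool,
                    bleb_fraction_range=(0.3, 0.8), n_bleb_range=(1, 3),
                    bleb_radius_range=(0.8, 2.5), roughness_amp_um=0.15,
                    ruffled_fraction=0.0,
                    body_intensity_range=(160.0, 200.0)) -> NucleusSpec:
    a = rng.uniform(4.5, 6.5)
    b = rng.uniform(3.5, min(a, 5.0))
    roughness = tuple((int(k), rng.uniform(0.3, 1.0) * roughness_amp_um,
                       rng.uniform(0, 2 * np.pi))
                      for k in rng.choice(np.arange(4, 9), size=2, replace=False))
    blebs = ()
    ruffle = 0.0
    if dysmorphic:
        n_blebs = int(rng.integers(n_bleb_range[0], n_bleb_range[1] + 1))
        angles = rng.uniform(0, 2 * np.pi) + np.arange(n_blebs) * (2 * np.pi / 3) \
            + rng.uniform(-0.3, 0.3, n_blebs)
        built = []
        for t in angles:
            radius = float(rng.uniform(*bleb_radius_range))
            built.append(BlebSpec(
                neck_angle=float(t), bleb_radius_um=radius,
                neck_width_um=float(radius * rng.uniform(0.8, 1.2)),
                intensity_fraction=float(rng.uniform(*bleb_fraction_range)),
                crevice_depth=float(rng.uniform(0.4, 0.6))))
        blebs = tuple(built)
        if rng.uniform() < ruffled_fraction:
            ruffle = float(rng.uniform(0.3, 0.5))
    return NucleusSpec(center_um=tuple(np.round(center_um, 3)),
                       semi_axes_um=(round(a, 3), round(b, 3)),
                       orientation_rad=float(round(rng.uniform(0, np.pi), 3)),
                       body_intensity=float(round(rng.uniform(*body_intensity_range), 1)),
                       blebs=blebs, ruffling_gradient=ruffle,
                       roughness=roughness,
                       class_label="dysmorphic" if dysmorphic else "normal")


def segmentation_fields(seed: int, n_normal: int = 50, n_dysmorphic: int = 50,
                        per_field: int = 10) -> list[FieldSpec]:
    """Fields for segmentation scoring: non-touching nuclei on a jittered grid."""
    rng = np.random.default_rng(seed)
    classes = ["normal"] * n_normal + ["dysmorphic"] * n_dysmorphic
    rng.shuffle(classes)
    ps = DEFAULT_PIXEL_SIZE_UM
    pitch_um, margin_um = 24.0, 12.0
    cols = 4
    rows = int(np.ceil(per_field / cols))
    w = int((2 * margin_um + cols * pitch_um) / ps)
    h = int((2 * margin_um + rows * pitch_um) / ps)
    fields = []
    for f0 in range(0, len(classes), per_field):
        chunk = classes[f0:f0 + per_field]
        nuclei = []
        for i, cls in enumerate(chunk):
            r, c = divmod(i, cols)
            cx = margin_um + (c + 0.5) * pitch_um + rng.uniform(-2, 2)
            cy = margin_um + (r + 0.5) * pitch_um + rng.uniform(-2, 2)
            nuclei.append(_random_nucleus(rng, (cx, cy), cls == "dysmorphic",
                                          bleb_fraction_range=(0.3, 0.6),
                                          bleb_radius_range=(1.2, 2.2),
                                          n_bleb_range=(1, 2),
                                          body_intensity_range=(90.0, 200.0)))
        fields.append(FieldSpec(shape_px=(h, w), pixel_size_um=ps,
                                nuclei=tuple(nuclei),
                                seed=int(rng.integers(2 ** 31))))
    return fields


def perturb_contour(contour: NucleusContour, rng: np.random.Generator,
                    amp_px_range=(1.0, 2.0), modes=(3, 5)) -> NucleusContour:
    """Smooth pseudo-observer perturbation: low-frequency normal offsets.

    Offsets are a 3-5 mode Fourier series along arc length with overall
    amplitude drawn from ``amp_px_range`` -- emulating inter-observer
    delineation variability without destroying the shape.
    """
    pts = resample_closed(contour.points, n=128)
    t = np.linspace(0, 2 * np.pi, len(pts), endpoint=False)
    n_modes = int(rng.integers(modes[0], modes[1] + 1))
    amp = rng.uniform(*amp_px_range)
    off = np.zeros(len(pts))
    weights = rng.uniform(0.5, 1.0, n_modes)
    phases = rng.uniform(0, 2 * np.pi, n_modes)
    for k, (wk, ph) in enumerate(zip(weights, phases), start=2):
        off += wk * np.cos(k * t + ph)
    off *= amp / max(np.abs(off).max(), 1e-9)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    nrm = np.hypot(tang[:, 0], tang[:, 1])
    normal = np.column_stack([tang[:, 1], -tang[:, 0]]) / nrm[:, None]
    new = pts + off[:, None] * normal
    return NucleusContour(points=new, stage=contour.stage,
                          nucleus_id=contour.nucleus_id, border=contour.border)


def pseudo_observers(contours: list[NucleusContour], seed: int,
                     n_observers: int = 3) -> GroundTruthSet:
    """Ground-truth set of K perturbed variants of the true contours."""
    rng = np.random.default_rng(seed)
    by_obs = {}
    for k in range(1, n_observers + 1):
        by_obs[k] = [perturb_contour(c, rng) for c in contours]
    return GroundTruthSet(contours_by_observer=by_obs)


def watershed_battery(seed: int, n_pairs: int = 20, n_blebbed: int = 20
                      ) -> list[dict]:
    """Split/merge decision battery.

    ``n_pairs`` touching nucleus pairs with a deep intensity valley
    (valley ratio <= 0.5, expected decision: split) and ``n_blebbed``
    single nuclei with a bright, barely dipping bleb neck (profile ratio
    >= 0.85, expected decision: merge).  Each item carries the field spec,
    the expected decision and the true nucleus count.
    """
    rng = np.random.default_rng(seed)
    ps = DEFAULT_PIXEL_SIZE_UM
    items = []
    for _ in range(n_pairs):
        r1, r2 = rng.uniform(4.0, 5.5, 2)
        gap = rng.uniform(-0.8, -0.4)             # slight overlap
        cx = 16.0 - (r1 + gap / 2)
        nuc_a = NucleusSpec(center_um=(round(cx, 3), 16.0),
                            semi_axes_um=(round(r1, 3), round(r1 * 0.9, 3)),
                            body_intensity=180.0)
        nuc_b = NucleusSpec(center_um=(round(cx + r1 + r2 + gap, 3), 16.0),
                            semi_axes_um=(round(r2, 3), round(r2 * 0.9, 3)),
                            body_intensity=180.0)
        ratio = float(round(rng.uniform(0.3, 0.5), 3))
        items.append({
            "spec": FieldSpec(shape_px=(160, 160), pixel_size_um=ps,
                              nuclei=(nuc_a, nuc_b),
                              touching_pairs=(TouchingPair(0, 1, ratio),),
                              gaussian_sd=2.0, seed=int(rng.integers(2 ** 31))),
            "expected": "split", "n_true": 2, "valley_ratio": ratio})
    for _ in range(n_blebbed):
        r = rng.uniform(4.5, 5.5)
        bleb = BlebSpec(neck_angle=float(rng.uniform(0, 2 * np.pi)),
                        bleb_radius_um=float(rng.uniform(1.8, 2.4)),
                        neck_width_um=float(rng.uniform(1.6, 2.0)),
                        intensity_fraction=1.0, crevice_depth=0.08)
        nuc = NucleusSpec(center_um=(16.0, 16.0),
                          semi_axes_um=(round(r, 3), round(r * 0.85, 3)),
                          orientation_rad=float(round(rng.uniform(0, np.pi), 3)),
                          body_intensity=180.0, blebs=(bleb,))
        items.append({
            "spec": FieldSpec(shape_px=(160, 160), pixel_size_um=ps,
                              nuclei=(nuc,), gaussian_sd=2.0,
                              seed=int(rng.integers(2 ** 31))),
            "expected": "merge", "n_true": 1})
    return items


def classification_specs(seed: int, n_per_class: int = 160) -> list[FieldSpec]:
    """One small field per nucleus for the feature / classification set.

    Half the dysmorphic nuclei additionally carry chromatin ruffling or
    chromocenters so texture features carry signal too.
    """
    rng = np.random.default_rng(seed)
    ps = DEFAULT_PIXEL_SIZE_UM
    out = []
    for cls in ("normal", "dysmorphic"):
        for _ in range(n_per_class):
            # mild cases on both sides: rough-edged normals and small-bleb
            # dysmorphics give the class overlap real data shows
            nuc = _random_nucleus(rng, (14.0, 14.0), cls == "dysmorphic",
                                  bleb_fraction_range=(0.5, 1.0),
                                  bleb_radius_range=(0.5, 2.2),
                                  roughness_amp_um=0.3,
                                  ruffled_fraction=0.5)
            if rng.uniform() < 0.3:
                k = int(rng.integers(2, 5))
                chromo = tuple(
                    (float(rng.uniform(-0.4, 0.4) * nuc.semi_axes_um[0]),
                     float(rng.uniform(-0.4, 0.4) * nuc.semi_axes_um[1]),
                     float(rng.uniform(0.4, 0.7)), float(rng.uniform(0.3, 0.5)))
                    for _ in range(k))
                nuc = NucleusSpec(**{**asdict_spec(nuc), "chromocenters": chromo})
            out.append(FieldSpec(shape_px=(140, 140), pixel_size_um=ps,
                                 nuclei=(nuc,), gaussian_sd=DEFAULT_GAUSSIAN_SD,
                                 seed=int(rng.integers(2 ** 31))))
    return out


def asdict_spec(nuc: NucleusSpec) -> dict:
    return {
        "center_um": nuc.center_um, "semi_axes_um": nuc.semi_axes_um,
        "orientation_rad": nuc.orientation_rad,
        "body_intensity": nuc.body_intensity, "blebs": nuc.blebs,
        "ruffling_gradient": nuc.ruffling_gradient,
        "chromocenters": nuc.chromocenters, "roughness": nuc.roughness,
        "class_label": nuc.class_label,
    }


def bleb_shape_family(n_steps: int = 10, max_amplitude_um: float = 3.0,
                      body_radius_um: float = 5.0,
                      bleb_radius_um: float = 1.8) -> list[NucleusContour]:
    """Analytic contour family with growing bleb amplitude (0 -> max, um).

    A fixed-size bleb circle emerges progressively from a 10 um nucleus
    body: amplitude is how far the bleb protrudes beyond the body boundary.
    Built from exact polygon unions (no raster) for shape-descriptor
    monotonicity studies: larger protrusions deviate more from an ellipse.
    """
    t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
    body = ShapelyPolygon(np.column_stack([
        body_radius_um * np.cos(t), 0.85 * body_radius_um * np.sin(t)]))
    out = []
    for i, h in enumerate(np.linspace(0.0, max_amplitude_um, n_steps)):
        if h < 1e-6:
            geom = body
        else:
            cx = body_radius_um - bleb_radius_um + h
            geom = body.union(Point(cx, 0).buffer(bleb_radius_um, quad_segs=64))
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        pts = np.asarray(geom.exterior.coords)[:-1]
        out.append(NucleusContour(points=pts * 5.0 + 40.0,  # px at 0.2 um/px
                                  stage="refined", nucleus_id=i + 1))
    return out


def gt_from_mask(mask: LabelMask) -> list[NucleusContour]:
    """Ground-truth contours traced from the rendered label mask."""
    return mask_to_contours(mask, stage="refined")


def manifest_for(seed: int, **sections) -> dict:
    man = {"seed": int(seed), "pixel_size_um": DEFAULT_PIXEL_SIZE_UM,
           "background": DEFAULT_BACKGROUND,
           "body_intensity": DEFAULT_BODY_INTENSITY}
    man.update(sections)
    return man


def standard_benchmark(seed: int) -> dict:
    """Specs for the fixed benchmark exercising every pipeline stage.

    Returns a dict of lazy spec collections plus a JSON-serializable
    manifest; deterministic given the seed.
    """
    seg = segmentation_fields(seed)
    battery = watershed_battery(seed + 1)
    cls = classification_specs(seed + 2)
    manifest = manifest_for(
        seed,
        segmentation={"n_fields": len(seg), "seeds": [f.seed for f in seg],
                      "n_nuclei": sum(len(f.nuclei) for f in seg)},
        watershed={"n_items": len(battery),
                   "n_split": sum(1 for i in battery if i["expected"] == "split")},
        classification={"n_fields": len(cls),
                        "per_class": len(cls) // 2},
    )
    return {"segmentation": seg, "watershed": battery,
            "classification": cls, "manifest": manifest}


def write_benchmark(bench: dict, out_dir) -> None:
    """Write benchmark images, ground truth and the manifest to a directory."""
    from pathlib import Path
    from .core import write_image
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "manifest.json").write_text(json.dumps(bench["manifest"], indent=2,
                                                  sort_keys=True))
    for i, fs in enumerate(bench["segmentation"]):
        img, mask, table = render_field(fs)
        write_image(img, out / f"seg_field_{i:02d}.tif")
        write_image(mask.labels, out / f"seg_field_{i:02d}_gt.tif",
                    pixel_size_um=fs.pixel_size_um)
        table.to_csv(out / f"seg_field_{i:02d}_labels.csv", index=False)
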