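"""Domain types, coordinate conventions and IO shared by every pipeline stage.

Conventions
-----------
* Images are 2-D rasters indexed ``pixels[y, x]`` (row = y, column = x),
  0-based; polygon vertices sit on pixel centers, so vertex ``(3.0, 5.0)``
  is the center of the pixel at row 5, column 3.
* Pixels are isotropic; every micrometre-valued parameter is converted to
  pixels through :func:`um_to_px`.
* Nucleus contours are stored counter-clockwise (positive shoelace area in
  (x, y) coordinates); the outward normal used by the contour-refinement
  stage is derived from this orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure

logger = logging.getLogger("nucseg")

STAGES = ("seed", "initial", "refined")


def um_to_px(value_um: float, pixel_size_um: float) -> int:
    """Convert a micrometre-valued parameter to whole pixels.

    Single authoritative conversion used pipeline-wide: ``round(um / px_size)``.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    return int(round(value_um / pixel_size_um))


@dataclass(frozen=True)
class CalibratedImage:
    """A 2-D intensity raster with its physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        Non-negative intensities, shape (rows, cols), at least 16 x 16.
    pixel_size_um : float
        Micrometres per pixel (isotropic, > 0).
    bit_depth : int
        Bit depth of the source data (informational).
    """

    pixels: np.ndarray
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"expected single channel 2-D image, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError(f"image too small: {px.shape}, need at least 16x16")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "CalibratedImage":
        return replace(self, pixels=pixels)


@dataclass
class NucleusContour:
    """Closed polygon outlining one nucleus, in pixel coordinates.

    ``points`` is an (n, 2) array of (x, y) vertices, n >= 8, stored
    counter-clockwise and implicitly closed.  ``stage`` records the
    lifecycle position: global-threshold component (``seed``),
    local-threshold outline (``initial``) or optimal-path refined outline
    (``refined``).
    """

    points: np.ndarray
    stage: str
    nucleus_id: int
    border: bool = False

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 8:
            raise ValueError("contour needs >= 8 (x, y) vertices")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if polygon_area(pts) < 0:  # stored CCW
            pts = pts[::-1].copy()
        if polygon_area(pts) <= 0:
            raise ValueError("contour encloses no area")
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def area_px(self) -> float:
        return polygon_area(self.points)

    def perimeter_px(self) -> float:
        return polygon_perimeter(self.points)

    def is_simple(self) -> bool:
        return ShapelyPolygon(self.points).is_simple

    def resample(self, max_spacing_px: float = 0.5) -> np.ndarray:
        """Vertices re-sampled at <= ``max_spacing_px`` arc spacing (closed)."""
        return resample_closed(self.points, max_spacing_px=max_spacing_px)


@dataclass
class LabelMask:
    """Integer raster twin of a set of nucleus ROIs: 0 = background, k = nucleus k."""

    labels: np.ndarray

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.min() < 0:
            raise ValueError("labels must be a 2-D non-negative integer array")
        self.labels = lab.astype(np.int32)

    @property
    def ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v > 0]


@dataclass
class GroundTruthSet:
    """Manual delineations from K >= 2 independent observers.

    ``contours_by_observer`` maps observer index (1..K) to a list of
    contours; nucleus correspondence across observers is by ``nucleus_id``.
    """

    contours_by_observer: Mapping[int, Sequence[NucleusContour]]

    def __post_init__(self):
        if len(self.contours_by_observer) < 2:
            raise ValueError("need at least 2 observers")
        ids = None
        for k, contours in self.contours_by_observer.items():
            these = {c.nucleus_id for c in contours}
            if ids is None:
                ids = these
            elif these != ids:
                raise ValueError(f"observer {k} nucleus_ids differ: {these ^ ids}")

    @property
    def observers(self) -> list[int]:
        return sorted(self.contours_by_observer)

    @property
    def nucleus_ids(self) -> list[int]:
        first = next(iter(self.contours_by_observer.values()))
        return sorted(c.nucleus_id for c in first)

    def contour(self, observer: int, nucleus_id: int) -> NucleusContour:
        for c in self.contours_by_observer[observer]:
            if c.nucleus_id == nucleus_id:
                return c
        raise KeyError(f"nucleus {nucleus_id} missing for observer {observer}")


# ---------------------------------------------------------------------------
# polygon geometry
# ---------------------------------------------------------------------------

def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area; positive for counter-clockwise vertex order."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polygon_perimeter(points: np.ndarray) -> float:
    pts = np.asarray(points, dtype=float)
    d = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def resample_closed(points: np.ndarray, n: int | None = None,
                    max_spacing_px: float | None = None) -> np.ndarray:
    """Resample a closed polygon to equally spaced vertices along its arc length."""
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise ValueError("degenerate contour")
    if n is None:
        if max_spacing_px is None:
            raise ValueError("give n or max_spacing_px")
        n = max(8, int(np.ceil(total / max_spacing_px)))
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, arc, closed[:, 0])
    y = np.interp(t, arc, closed[:, 1])
    return np.column_stack([x, y])


def simplify_collinear(points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Drop vertices lying on the segment joining their neighbours."""
    pts = np.asarray(points, dtype=float)
    keep = np.ones(len(pts), dtype=bool)
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    cross = (nxt[:, 0] - prev[:, 0]) * (pts[:, 1] - prev[:, 1]) \
        - (nxt[:, 1] - prev[:, 1]) * (pts[:, 0] - prev[:, 0])
    keep[np.abs(cross) < tol] = False
    if keep.sum() < 8:
        return pts
    return pts[keep]


# ---------------------------------------------------------------------------
# raster <-> contour conversion
# ---------------------------------------------------------------------------

def _rasterize(points: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Binary mask of pixels whose centers fall inside the polygon."""
    pts = np.asarray(points, dtype=float)
    x0 = max(0, int(np.floor(pts[:, 0].min())))
    x1 = min(shape[1] - 1, int(np.ceil(pts[:, 0].max())))
    y0 = max(0, int(np.floor(pts[:, 1].min())))
    y1 = min(shape[0] - 1, int(np.ceil(pts[:, 1].max())))
    out = np.zeros(shape, dtype=bool)
    if x1 < x0 or y1 < y0:
        return out
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    centers = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    inside = MplPath(pts).contains_points(centers)
    out[y0:y1 + 1, x0:x1 + 1] = inside.reshape(ys.shape)
    return out


def contours_to_mask(contours: Iterable[NucleusContour],
                     shape: tuple[int, int]) -> LabelMask:
    """Rasterize contours into a label mask (pixel-center-inside rule).

    Raises if two contours claim the same pixel, naming the offenders.
    """
    labels = np.zeros(shape, dtype=np.int32)
    for c in contours:
        m = _rasterize(c.points, shape)
        clash = labels[m]
        clash = clash[clash > 0]
        if clash.size:
            raise ValueError(
                f"overlapping contours: nucleus_ids {sorted(set(clash.tolist()))} "
                f"and {c.nucleus_id}")
        labels[m] = c.nucleus_id
    return LabelMask(labels)


def mask_to_contours(mask: LabelMask, stage: str = "initial") -> list[NucleusContour]:
    """Trace the outer boundary of each label as a CCW polygon.

    Uses marching squares at the 0.5 level with full (8-) connectivity, so
    diagonally linked pixels stay in one contour; the longest ring per label
    is taken as the outer boundary.
    """
    out = []
    for k in mask.ids:
        binary = (mask.labels == k).astype(float)
        rings = measure.find_contours(binary, 0.5, fully_connected="high")
        if not rings:
            continue
        ring = max(rings, key=len)           # (row, col) vertices
        pts = np.column_stack([ring[:, 1], ring[:, 0]])
        if np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 8:
            pts = resample_closed(pts, n=8)
        out.append(NucleusContour(points=pts, stage=stage, nucleus_id=k))
    return out


# ---------------------------------------------------------------------------
# file IO
# ---------------------------------------------------------------------------

def read_image(path: str | Path, pixel_size_override: float | None = None) -> CalibratedImage:
    """Read a single-channel 2-D TIFF (or PNG fixture) as a CalibratedImage.

    Pixel size comes from TIFF resolution metadata when present; an explicit
    ``pixel_size_override`` wins; with neither, 1.0 um/px is assumed with a
    warning.  Multi-channel or 3-D data is rejected.
    """
    path = Path(path)
    pixel_size = None
    if path.suffix.lower() in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is not None:
                num, den = res.value
                if num > 0 and den > 0:
                    per_unit = num / den
                    unit_um = {2: 25400.0, 3: 10000.0}.get(
                        getattr(unit, "value", None) and int(unit.value), None)
                    if unit_um:
                        pixel_size = unit_um / per_unit
            xr = None
            try:
                xr = page.tags["ImageDescription"].value
            except KeyError:
                pass
            if pixel_size is None and xr and "pixel_size_um=" in xr:
                pixel_size = float(xr.split("pixel_size_um=")[1].split()[0])
    else:
        import imageio.v3 as iio
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise ValueError(f"expected single channel 2-D image, got shape {arr.shape}")
    if pixel_size_override is not None:
        pixel_size = float(pixel_size_override)
    if pixel_size is None:
        warnings.warn(f"{path.name}: no pixel size metadata; assuming 1.0 um/px")
        pixel_size = 1.0
    bit_depth = arr.dtype.itemsize * 8 if arr.dtype.kind in "ui" else 16
    return CalibratedImage(pixels=arr.astype(float),
                           pixel_size_um=pixel_size, bit_depth=bit_depth)


def write_image(image: CalibratedImage | np.ndarray, path: str | Path,
                pixel_size_um: float | None = None) -> None:
    """Write an intensity image or label raster as 16-bit TIFF with calibration."""
    if isinstance(image, CalibratedImage):
        arr = image.pixels
        pixel_size_um = image.pixel_size_um
    else:
        arr = np.asarray(image)
    arr16 = np.clip(np.round(arr), 0, 65535).astype(np.uint16)
    kwargs = {}
    if pixel_size_um:
        per_cm = 10000.0 / pixel_size_um
        kwargs = dict(resolution=(per_cm, per_cm), resolutionunit=3,
                      description=f"pixel_size_um={pixel_size_um}")
    tifffile.imwrite(Path(path), arr16, **kwargs)


def contours_to_table(contours: Iterable[NucleusContour]) -> pd.DataFrame:
    rows = []
    for c in contours:
        for i, (x, y) in enumerate(c.points):
            rows.append((c.nucleus_id, i, x, y, c.stage))
    return pd.DataFrame(rows, columns=["nucleus_id", "vertex_index", "x", "y", "stage"])


def table_to_contours(df: pd.DataFrame) -> list[NucleusContour]:
    out = []
    for nid, grp in df.groupby("nucleus_id"):
        grp = grp.sort_values("vertex_index")
        out.append(NucleusContour(points=grp[["x", "y"]].to_numpy(),
                                  stage=str(grp["stage"].iloc[0]),
                                  nucleus_id=int(nid)))
    return out


def write_results(contours: Sequence[NucleusContour], table: pd.DataFrame | None,
                  out_dir: str | Path, shape: tuple[int, int],
                  pixel_size_um: float = 1.0) -> dict[str, Path]:
    """Write label mask (16-bit TIFF), contour CSV and feature/metric CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mask": out_dir / "labels.tif",
        "contours": out_dir / "contours.csv",
        "table": out_dir / "table.csv",
    }
    mask = contours_to_mask(contours, shape)
    write_image(mask.labels, paths["mask"], pixel_size_um=pixel_size_um)
    contours_to_table(contours).to_csv(paths["contours"], index=False)
    if table is None:
        table = pd.DataFrame(columns=["nucleus_id"])
    table.to_csv(paths["table"], index=False)
    return paths
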