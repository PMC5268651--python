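"""Contour refinement by band straightening and optimal-path finding.

A 2 um wide band around the current contour (1 um to each side) is
resampled into a rectangular matrix (rows = normal offsets, columns = arc
positions), the nuclear edge is enhanced with a vertical Sobel derivative,
columns are normalized to their maxima so dim bleb edges weigh as much as
bright body edges, and the boundary is re-detected as the left-to-right
path maximizing the *path strength* -- the ratio of summed normalized edge
intensity (gain) to path length in traversed cells (loss).  Vertical runs
of any height are allowed (propagation up to 90 degrees), which is what
lets the path descend into crevices around blebs.  The procedure is
iterated so indentations deeper than the band half-width are reached.

Two path solvers are provided:

* :func:`eq1_matrices` -- the per-element greedy recursion that keeps, for
  every matrix element, only the strongest incoming path (strength, gain
  and loss matrices S, G, L).  Exposed for diagnostics.
* :func:`optimal_path` -- an exact maximizer of the stated ratio objective
  over all column-monotone paths, via Dinkelbach parametric linearization
  (iterated additive DP on gain - lambda * loss).  The greedy recursion is
  not an exact ratio maximizer -- keeping only the best-ratio prefix at a
  node discards higher-loss prefixes that can win after a weak suffix --
  so the exact solver drives the refinement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from shapely.geometry import Polygon as ShapelyPolygon

from .core import (CalibratedImage, NucleusContour, resample_closed,
                   simplify_collinear, um_to_px)

logger = logging.getLogger("nucseg")


@dataclass
class StraightenedBand:
    """q x r sampling of the peri-contour band.

    Row 0 is the innermost offset (-half_width), row q-1 the outermost
    (+half_width); the middle row lies on the input contour.  ``anchors``
    holds per-column (x, y, nx, ny): contour point and outward unit normal.
    """

    values: np.ndarray
    anchors: np.ndarray            # (r, 4): x, y, nx, ny
    half_width_um: float
    row_step_px: float = 1.0

    @property
    def q(self) -> int:
        return self.values.shape[0]

    @property
    def r(self) -> int:
        return self.values.shape[1]


@dataclass
class PathMatrices:
    """State of the path search on a normalized band matrix N."""

    N: np.ndarray
    S: np.ndarray
    G: np.ndarray
    L: np.ndarray
    path: np.ndarray               # per-column row index of the optimal path
    strength: float


@dataclass(frozen=True)
class RefineConfig:
    half_width_um: float = 1.0     # 2 um band total
    max_iterations: int = 5
    convergence_tol_px: float = 0.5

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


# ---------------------------------------------------------------------------
# band construction
# ---------------------------------------------------------------------------

def straighten_band(image: CalibratedImage, contour: NucleusContour,
                    half_width_um: float = 1.0) -> StraightenedBand:
    """Straighten the peri-contour band into a q x r matrix.

    The contour is resampled to ``r = max(32, round(perimeter_px))`` equally
    spaced arc positions through a periodic cubic spline (which also yields
    smooth outward normals); at each position, q samples are taken along the
    normal by cubic interpolation, clamped to edge values at image borders.
    """
    if contour.n_points < 8:
        raise ValueError("contour needs >= 8 vertices")
    r = max(32, int(round(contour.perimeter_px())))
    pts = resample_closed(contour.points, n=r)
    # light smoothing irons out raster staircase before taking derivatives
    try:
        tck, _ = splprep([pts[:, 0], pts[:, 1]], per=1, s=0.5 * r * 0.25 ** 2)
        u = np.linspace(0, 1, r, endpoint=False)
        x, y = splev(u, tck)
        dx, dy = splev(u, tck, der=1)
    except Exception:                      # near-degenerate input: linear fallback
        x, y = pts[:, 0], pts[:, 1]
        d = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        dx, dy = d[:, 0], d[:, 1]
    norm = np.hypot(dx, dy)
    norm[norm == 0] = 1.0
    # CCW contour: outward normal of tangent (tx, ty) is (ty, -tx)
    nx, ny = dy / norm, -dx / norm
    m = max(1, um_to_px(half_width_um, image.pixel_size_um))
    offsets = np.arange(-m, m + 1, dtype=float)
    sx = x[None, :] + offsets[:, None] * nx[None, :]
    sy = y[None, :] + offsets[:, None] * ny[None, :]
    values = ndimage.map_coordinates(image.pixels, [sy, sx], order=3,
                                     mode="nearest")
    anchors = np.column_stack([x, y, nx, ny])
    return StraightenedBand(values=values, anchors=anchors,
                            half_width_um=half_width_um, row_step_px=1.0)


def edge_derivative(band: StraightenedBand) -> StraightenedBand:
    """Vertical Sobel response, signed bright-inside -> dark-outside positive.

    Intensity falls with increasing row index at the true boundary, so the
    response is the negated row derivative; negative responses (dark-inside
    transitions, e.g. debris) are clamped to zero.
    """
    if band.q < 3:
        raise ValueError("band needs q >= 3 rows")
    v = np.concatenate([band.values[:, -1:], band.values, band.values[:, :1]], axis=1)
    resp = -ndimage.sobel(v, axis=0, mode="nearest")[:, 1:-1]
    return StraightenedBand(values=np.clip(resp, 0, None), anchors=band.anchors,
                            half_width_um=band.half_width_um,
                            row_step_px=band.row_step_px)


def normalize_columns(P: np.ndarray) -> np.ndarray:
    """Divide each column by its maximum; all-zero columns stay zero."""
    P = np.asarray(P, dtype=float)
    if (P < 0).any():
        raise ValueError("P must be non-negative")
    mx = P.max(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        N = np.where(mx > 0, P / mx, 0.0)
    return N


# ---------------------------------------------------------------------------
# path finding
# ---------------------------------------------------------------------------

def _run_sums(N_prev: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vertical-run gain and cell count between rows of the previous column.

    ``run[i, k]`` sums N_prev over cells x in [i, k[ -- from the landing row
    i toward predecessor k, including i, excluding k; ``cnt[i, k] = |i - k|``.
    """
    q = len(N_prev)
    csum = np.concatenate([[0.0], np.cumsum(N_prev)])
    i = np.arange(q)[:, None]
    k = np.arange(q)[None, :]
    run = np.where(i < k, csum[k] - csum[i],
                   np.where(i > k, csum[i + 1] - csum[k + 1], 0.0))
    cnt = np.abs(i - k).astype(float)
    return run, cnt


_TIE_TOL = 1e-9   # floats summed in different orders can differ by ulps


def _argbest(score: np.ndarray) -> np.ndarray:
    """Per-row argmax over k; ties -> smallest |i-k|, then smaller k."""
    q = score.shape[0]
    best = np.empty(q, dtype=int)
    for i in range(q):
        row = score[i]
        cand = np.flatnonzero(row >= row.max() - _TIE_TOL)
        if len(cand) > 1:
            disp = np.abs(cand - i)
            cand = cand[disp == disp.min()]
        best[i] = cand[0]
    return best


def eq1_matrices(N: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Greedy per-element strength recursion: S, G, L and predecessor matrix.

    First column: S = G = N, L = 1.  Each element keeps the predecessor
    maximizing (gain + run + own cell) / (loss + run cells + 1); ties break
    toward the smallest vertical displacement, then the smaller row index.
    """
    N = np.asarray(N, dtype=float)
    q, r = N.shape
    G = np.zeros((q, r))
    L = np.ones((q, r))
    S = np.zeros((q, r))
    pred = np.zeros((q, r), dtype=int)
    G[:, 0] = N[:, 0]
    S[:, 0] = G[:, 0] / L[:, 0]
    for j in range(1, r):
        run, cnt = _run_sums(N[:, j - 1])
        gain = G[:, j - 1][None, :] + run + N[:, j][:, None]
        loss = L[:, j - 1][None, :] + cnt + 1.0
        s = gain / loss
        d = _argbest(s)
        rows = np.arange(q)
        pred[:, j] = d
        G[:, j] = gain[rows, d]
        L[:, j] = loss[rows, d]
        S[:, j] = s[rows, d]
    return S, G, L, pred


def greedy_path(N: np.ndarray) -> tuple[np.ndarray, float]:
    """Path from the greedy recursion: backtrace from the best final element."""
    S, G, L, pred = eq1_matrices(N)
    q, r = N.shape
    path = np.zeros(r, dtype=int)
    path[-1] = int(np.argmax(S[:, -1]))
    for j in range(r - 1, 0, -1):
        path[j - 1] = pred[path[j], j]
    return path, float(S[path[-1], -1])


def path_gain_loss(N: np.ndarray, rows: np.ndarray) -> tuple[float, float]:
    """Gain and loss of an explicit path, from the run semantics directly."""
    N = np.asarray(N, dtype=float)
    rows = np.asarray(rows, dtype=int)
    g = float(N[rows[0], 0])
    l = 1.0
    for j in range(1, len(rows)):
        i, k = rows[j], rows[j - 1]
        if i < k:
            cells = range(i, k)
        elif i > k:
            cells = range(k + 1, i + 1)
        else:
            cells = range(0)
        g += sum(N[x, j - 1] for x in cells) + N[i, j]
        l += abs(i - k) + 1.0
    return g, l


def _linear_dp(N: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Exact additive DP: maximize gain - lam * loss over monotone paths."""
    q, r = N.shape
    V = N[:, 0] - lam * 1.0
    preds = np.zeros((q, r), dtype=int)
    for j in range(1, r):
        run, cnt = _run_sums(N[:, j - 1])
        score = V[None, :] + run - lam * cnt + N[:, j][:, None] - lam
        d = _argbest(score)
        preds[:, j] = d
        V = score[np.arange(q), d]
    path = np.zeros(r, dtype=int)
    path[-1] = int(np.flatnonzero(V >= V.max() - _TIE_TOL)[0])
    for j in range(r - 1, 0, -1):
        path[j - 1] = preds[path[j], j]
    return path, float(V.max())


def optimal_path(N: np.ndarray) -> PathMatrices:
    """Globally optimal column-monotone path maximizing gain / loss.

    Dinkelbach iteration: starting from the greedy path's strength, solve
    the additive surrogate max(gain - lambda * loss), update lambda to the
    winning path's ratio, and stop when the surrogate optimum reaches zero.
    Finite path set => finite, exact convergence.  The greedy S/G/L
    matrices are returned for inspection alongside the exact path.
    """
    N = np.asarray(N, dtype=float)
    if N.ndim != 2 or N.shape[1] < 2:
        raise ValueError("N must be q x r with r >= 2")
    if N.min() < 0 or N.max() > 1 + 1e-12:
        raise ValueError("N entries must lie in [0, 1]")
    q, r = N.shape
    S, G, L, _ = eq1_matrices(N)
    path, lam = greedy_path(N)
    for _ in range(64):
        cand, _value = _linear_dp(N, lam)
        g, l = path_gain_loss(N, cand)
        if g / l <= lam + 1e-15:
            break                      # no path beats the current ratio
        path, lam = cand, g / l
    g, l = path_gain_loss(N, path)
    return PathMatrices(N=N, S=S, G=G, L=L, path=path, strength=g / l)


def brute_force_path(N: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive enumeration of every column-monotone path (test oracle).

    Ties (distinct paths with identical strength, which arise structurally
    because every normalized column attains 1.0) are broken by the same rule
    the solver's backtrace applies: smallest row in the last column, then,
    walking backwards, smallest vertical displacement and finally smaller
    row index.  Intended for tiny matrices only (q^r paths).
    """
    import itertools
    N = np.asarray(N, dtype=float)
    q, r = N.shape
    scored = []
    for rows in itertools.product(range(q), repeat=r):
        g, l = path_gain_loss(N, np.array(rows))
        scored.append((g / l, rows))
    best_s = max(s for s, _ in scored)
    cands = [rows for s, rows in scored if s >= best_s - 1e-12]
    last = min(rows[-1] for rows in cands)
    cands = [rows for rows in cands if rows[-1] == last]
    for j in range(r - 2, -1, -1):
        key = min((abs(rows[j] - rows[j + 1]), rows[j]) for rows in cands)
        cands = [rows for rows in cands
                 if (abs(rows[j] - rows[j + 1]), rows[j]) == key]
    return np.array(cands[0]), best_s


# ---------------------------------------------------------------------------
# contour reconstruction and iteration
# ---------------------------------------------------------------------------

def _closed_path(N: np.ndarray) -> np.ndarray:
    """Path on the circular band: wrap-extend, solve, unwrap, blend the seam.

    The band is circular in arc position but the path model is an open
    left-to-right sweep, so the first ceil(r/10) columns are appended at the
    right edge to give the path closure context; the duplicate is dropped
    and any residual start/end row mismatch is blended linearly over the
    final 5% of columns (yielding fractional rows).
    """
    q, r = N.shape
    w = int(np.ceil(r / 10))
    ext = np.concatenate([N, N[:, :w]], axis=1)
    pm = optimal_path(ext)
    p = pm.path[:r].astype(float)
    wrapped_start = pm.path[r] if w > 0 else p[0]
    # continuity target: the wrapped copy of column 0
    mismatch = p[0] - p[r - 1]
    if abs(p[0] - wrapped_start) <= abs(mismatch):
        target = float(wrapped_start)
    else:
        target = p[0]
    k = max(2, int(round(0.05 * r)))
    alpha = np.linspace(0, 1, k, endpoint=True)
    tail = p[r - k:r]
    p[r - k:r] = tail + alpha * (target - tail[-1]) * (alpha)
    return p


def reconstruct_contour(path: np.ndarray, band: StraightenedBand,
                        nucleus_id: int = 0) -> NucleusContour:
    """Map per-column path rows back to image coordinates.

    Row ``(q-1)/2`` is offset 0 (the input contour); each row step is one
    pixel along the column's outward normal.  Collinear runs are removed.
    Raises ValueError if the resulting polygon self-intersects (callers fall
    back to the pre-refinement contour).
    """
    rows = np.asarray(path, dtype=float)
    if len(rows) != band.r:
        raise ValueError("path length must equal the number of band columns")
    mid = (band.q - 1) / 2.0
    off = (rows - mid) * band.row_step_px
    x = band.anchors[:, 0] + off * band.anchors[:, 2]
    y = band.anchors[:, 1] + off * band.anchors[:, 3]
    pts = simplify_collinear(np.column_stack([x, y]))
    poly = ShapelyPolygon(pts)
    if not poly.is_valid or not poly.is_simple:
        # normals converging in concave stretches create small local loops;
        # drop them and keep the dominant ring
        repaired = poly.buffer(0)
        if repaired.geom_type == "MultiPolygon":
            repaired = max(repaired.geoms, key=lambda g: g.area)
        if repaired.is_empty or repaired.area < 0.5 * abs(poly.area):
            raise ValueError("refined contour self-intersects beyond repair")
        pts = np.asarray(repaired.exterior.coords)[:-1]
        pts = simplify_collinear(pts)
        if len(pts) < 8:
            raise ValueError("refined contour degenerate after repair")
    return NucleusContour(points=pts, stage="refined", nucleus_id=nucleus_id)


def refine(image: CalibratedImage, contour: NucleusContour,
           cfg: RefineConfig = RefineConfig()) -> tuple[NucleusContour, int, bool]:
    """Iterate straighten -> derivative -> normalize -> path -> reconstruct.

    Stops when the maximum boundary displacement in an iteration falls
    below ``convergence_tol_px`` or after ``max_iterations``.  If a
    reconstruction self-intersects, the pre-refinement contour of that
    iteration is kept and iteration stops.
    """
    current = contour
    converged = False
    it = 0
    for it in range(1, cfg.max_iterations + 1):
        band = straighten_band(image, current, cfg.half_width_um)
        P = edge_derivative(band)
        N = normalize_columns(P.values)
        if N.max() <= 0:       # featureless band: nothing to refine against
            converged = True
            break
        path = _closed_path(N)
        try:
            new = reconstruct_contour(path, band, nucleus_id=contour.nucleus_id)
        except ValueError:
            logger.warning("nucleus %d: refined contour self-intersects; "
                           "keeping previous contour", contour.nucleus_id)
            break
        new.border = contour.border
        mid = (band.q - 1) / 2.0
        displacement = float(np.max(np.abs(path - mid)) * band.row_step_px)
        current = new
        if displacement < cfg.convergence_tol_px:
            converged = True
            break
    return current, it, converged
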