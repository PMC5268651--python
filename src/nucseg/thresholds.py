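"""Automatic intensity threshold registry.

All methods are deterministic functions of a 256-bin histogram built over
the min-max range of the supplied pixel population, matching ImageJ's
auto-threshold behaviour regardless of bit depth.  Thresholding downstream
is always ``pixel >= threshold`` = foreground.

Registered methods: huang, isodata, li, max_entropy, mean, otsu, triangle,
yen -- the set carrying the method's headline settings plus the common
defaults.  Further ImageJ methods can be added via :func:`register`.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

N_BINS = 256


class DegenerateHistogramError(ValueError):
    """Raised when a pixel population has fewer than 2 distinct values."""


def _histogram(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """256-bin histogram (counts, centers) over the population min-max range."""
    vals = np.asarray(pixels, dtype=float).ravel()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateHistogramError("degenerate histogram: constant population")
    counts, edges = np.histogram(vals, bins=N_BINS, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def _split_value(centers: np.ndarray, t: int) -> float:
    """Threshold value at the upper edge of background bin ``t``."""
    w = centers[1] - centers[0]
    return float(centers[t] + 0.5 * w)


def _mean(counts, centers):
    return float(np.sum(counts * centers) / counts.sum())


def _otsu(counts, centers):
    total = counts.sum()
    w = np.cumsum(counts)
    mu = np.cumsum(counts * centers)
    mu_t = mu[-1]
    var = np.full(N_BINS - 1, -1.0)
    for t in range(N_BINS - 1):
        w0, w1 = w[t], total - w[t]
        if w0 == 0 or w1 == 0:
            continue
        m0 = mu[t] / w0
        m1 = (mu_t - mu[t]) / w1
        var[t] = w0 * w1 * (m0 - m1) ** 2
    # empty bins between well-separated modes make the maximum a flat
    # plateau; take its middle bin so the cut sits centrally in the valley
    plateau = np.flatnonzero(var >= var.max() * (1 - 1e-10))
    return _split_value(centers, int(plateau[(len(plateau) - 1) // 2]))


def _isodata(counts, centers):
    # Ridler-Calvard iterative intermeans on the histogram
    t = int(np.flatnonzero(counts)[0])
    prev = -1
    w = np.cumsum(counts)
    mu = np.cumsum(counts * centers)
    while t != prev:
        prev = t
        w0, w1 = w[t], w[-1] - w[t]
        if w0 == 0 or w1 == 0:
            t += 1 if w0 == 0 else -1
            continue
        m0 = mu[t] / w0
        m1 = (mu[-1] - mu[t]) / w1
        mid = 0.5 * (m0 + m1)
        t = int(np.searchsorted(centers, mid))
        t = min(max(t, 0), N_BINS - 2)
    return _split_value(centers, t)


def _li(counts, centers):
    # iterative minimum cross-entropy (Li & Tam 1998)
    shifted = centers - centers[0] + (centers[1] - centers[0])  # keep values > 0
    mean_all = np.sum(counts * shifted) / counts.sum()
    t_val = mean_all
    for _ in range(100):
        below = shifted <= t_val
        w0 = counts[below].sum()
        w1 = counts[~below].sum()
        if w0 == 0 or w1 == 0:
            break
        m0 = np.sum(counts[below] * shifted[below]) / w0
        m1 = np.sum(counts[~below] * shifted[~below]) / w1
        new_t = (m0 - m1) / (np.log(m0) - np.log(m1))
        if abs(new_t - t_val) < 0.5 * (centers[1] - centers[0]):
            t_val = new_t
            break
        t_val = new_t
    return float(t_val + centers[0] - (centers[1] - centers[0]))


def _triangle(counts, centers):
    # max distance between histogram and the peak-to-tail line (ImageJ form:
    # the histogram is flipped so the longer tail lies left of the peak)
    hist = counts.copy()
    peak = int(np.argmax(hist))
    nz = np.flatnonzero(hist)
    lo, hi = int(nz[0]), int(nz[-1])
    flip = (peak - lo) < (hi - peak)
    if flip:
        hist = hist[::-1]
        lo = N_BINS - hi - 1
        peak = N_BINS - peak - 1
    width = peak - lo
    if width <= 0:
        t = peak
    else:
        x = np.arange(width)
        y = hist[x + lo]
        norm = np.hypot(hist[peak], width)
        d = (hist[peak] * x - width * y) / norm
        t = int(np.argmax(d)) + lo
    if flip:
        t = N_BINS - t - 1
    return _split_value(centers, min(t, N_BINS - 2))


def _max_entropy(counts, centers):
    # Kapur-Sahoo-Wong: maximize background + foreground Shannon entropies
    p = counts / counts.sum()
    P = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    H = np.cumsum(plogp)
    best, best_t = -np.inf, 0
    for t in range(N_BINS - 1):
        w0, w1 = P[t], 1 - P[t]
        if w0 <= 0 or w1 <= 0:
            continue
        hb = np.log(w0) - H[t] / w0
        hf = np.log(w1) - (H[-1] - H[t]) / w1
        if hb + hf > best:
            best, best_t = hb + hf, t
    return _split_value(centers, best_t)


def _huang(counts, centers):
    # Huang & Wang fuzzy thresholding (Shannon entropy of membership)
    w = np.cumsum(counts)
    mu = np.cumsum(counts * centers)
    total, mu_t = w[-1], mu[-1]
    nz = np.flatnonzero(counts)
    c = 1.0 / max(centers[nz[-1]] - centers[nz[0]], 1e-12)
    best, best_t = np.inf, 0
    for t in range(N_BINS - 1):
        w0, w1 = w[t], total - w[t]
        if w0 == 0 or w1 == 0:
            continue
        m0 = mu[t] / w0
        m1 = (mu_t - mu[t]) / w1
        mu_x = np.where(np.arange(N_BINS) <= t,
                        1.0 / (1.0 + c * np.abs(centers - m0)),
                        1.0 / (1.0 + c * np.abs(centers - m1)))
        mu_x = np.clip(mu_x, 1e-12, 1 - 1e-12)
        s = -mu_x * np.log(mu_x) - (1 - mu_x) * np.log(1 - mu_x)
        e = float(np.sum(s * counts))
        if e < best:
            best, best_t = e, t
    return _split_value(centers, best_t)


def _yen(counts, centers):
    p = counts / counts.sum()
    P = np.cumsum(p)
    P2 = np.cumsum(p * p)
    best, best_t = -np.inf, 0
    for t in range(N_BINS - 1):
        w0, w1 = P[t], 1 - P[t]
        s0, s1 = P2[t], P2[-1] - P2[t]
        if w0 <= 0 or w1 <= 0 or s0 <= 0 or s1 <= 0:
            continue
        crit = -np.log(s0 * s1) + 2 * np.log(w0 * w1)
        if crit > best:
            best, best_t = crit, t
    return _split_value(centers, best_t)


_REGISTRY: dict[str, Callable[[np.ndarray, np.ndarray], float]] = {
    "huang": _huang,
    "isodata": _isodata,
    "li": _li,
    "max_entropy": _max_entropy,
    "mean": _mean,
    "otsu": _otsu,
    "triangle": _triangle,
    "yen": _yen,
}


def register(name: str, fn: Callable[[np.ndarray, np.ndarray], float]) -> None:
    _REGISTRY[name] = fn


def available_methods() -> list[str]:
    return sorted(_REGISTRY)


def auto_threshold(pixels: np.ndarray, method: str) -> float:
    """Threshold for a pixel population via the named histogram method.

    Raises :class:`DegenerateHistogramError` on constant input (callers may
    fall back, e.g. to a global threshold) and KeyError on unknown methods.
    The returned value always lies within the population's [min, max].
    """
    if method not in _REGISTRY:
        raise KeyError(f"unknown threshold method {method!r}; "
                       f"available: {available_methods()}")
    counts, centers = _histogram(pixels)
    value = _REGISTRY[method](counts, centers)
    vals = np.asarray(pixels, dtype=float)
    return float(np.clip(value, vals.min(), vals.max()))
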