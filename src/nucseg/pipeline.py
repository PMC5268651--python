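"""End-to-end pipeline and exploratory analysis.

Stage order: preprocess -> two-pass segmentation -> contour refinement ->
conditional watershed (newly split contours are re-refined, closing the
loop) -> feature extraction -> optional classification.  Every refined
contour traces back to exactly one seed or one accepted watershed split
(the lineage is logged).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .config import PipelineConfig
from .core import CalibratedImage, NucleusContour
from .features import extract_all
from .preprocess import preprocess
from .refine import refine
from .segment import segment_twopass
from .watershed import conditional_split

logger = logging.getLogger("nucseg")


@dataclass
class PipelineResult:
    contours: list[NucleusContour]
    features: pd.DataFrame
    lineage: pd.DataFrame
    predictions: pd.DataFrame | None = None
    timings: dict = field(default_factory=dict)


def run_pipeline(image: CalibratedImage, cfg: PipelineConfig,
                 model=None) -> PipelineResult:
    """Run the full segmentation / feature / classification pipeline."""
    timings = {}
    t0 = time.perf_counter()
    pre = preprocess(image, cfg.preprocess.build())
    timings["preprocess"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    initial, _dilated = segment_twopass(pre, cfg.segment.build())
    timings["segment"] = time.perf_counter() - t0
    logger.info("segmentation: %d initial contours", len(initial))

    refine_cfg = cfg.refine.build() if cfg.refine.enabled else None
    t0 = time.perf_counter()
    refined = []
    for c in initial:
        if refine_cfg is not None:
            rc, n_it, conv = refine(pre, c, refine_cfg)
            logger.debug("nucleus %d refined in %d iterations (converged=%s)",
                         c.nucleus_id, n_it, conv)
        else:
            rc = c
        refined.append(rc)
    timings["refine"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    final: list[NucleusContour] = []
    lineage = []
    next_id = max((c.nucleus_id for c in refined), default=0) + 1
    if cfg.watershed.enabled:
        ws_cfg = cfg.watershed.build()
        for c in refined:
            pieces = conditional_split(pre, c, ws_cfg, refine_cfg=refine_cfg)
            if len(pieces) == 1:
                pieces[0].nucleus_id = c.nucleus_id
                lineage.append((c.nucleus_id, c.nucleus_id, "kept"))
            else:
                for p in pieces:
                    p.nucleus_id = next_id
                    lineage.append((next_id, c.nucleus_id, "split"))
                    next_id += 1
            final.extend(pieces)
    else:
        final = refined
        lineage = [(c.nucleus_id, c.nucleus_id, "kept") for c in final]
    timings["watershed"] = time.perf_counter() - t0
    logger.info("watershed: %d final contours", len(final))

    t0 = time.perf_counter()
    feats = extract_all(pre, final, cfg.features.build())
    timings["features"] = time.perf_counter() - t0

    predictions = None
    if model is not None and len(feats):
        from .classify import predict
        predictions = predict(model, feats)

    lineage_df = pd.DataFrame(lineage, columns=["nucleus_id", "parent_id", "origin"])
    for stage, dt in timings.items():
        logger.info("stage %-10s %.2fs", stage, dt)
    return PipelineResult(contours=final, features=feats, lineage=lineage_df,
                          predictions=predictions, timings=timings)


# ---------------------------------------------------------------------------
# exploratory clustering / PCA
# ---------------------------------------------------------------------------

@dataclass
class ExploreReport:
    cluster_assignments: np.ndarray
    correspondence: float | None
    pca_variance_ratio: np.ndarray
    pca_loadings: pd.DataFrame
    dropped_columns: list[str]
    caveat: str = ("Ward linkage computed on Manhattan distances as specified; "
                   "note Ward's objective classically assumes squared Euclidean "
                   "distances.")


def explore(features: pd.DataFrame, labels: pd.Series | None = None,
            n_clusters: int = 2) -> ExploreReport:
    """Hierarchical clustering (Ward on Manhattan) and PCA of z-scored features.

    Cluster/label correspondence is the best match over label permutations.
    Constant columns are dropped with a warning.
    """
    X = features.select_dtypes(include=[np.number]).drop(
        columns=[c for c in ("nucleus_id", "border") if c in features],
        errors="ignore")
    if len(X) < 10:
        raise ValueError("need >= 10 rows to explore")
    std = X.std(ddof=0)
    dropped = list(X.columns[std == 0])
    if dropped:
        logger.warning("dropping constant feature columns: %s", dropped)
        X = X.drop(columns=dropped)
        std = std.drop(labels=dropped)
    Z = (X - X.mean()) / std
    d = pdist(Z.to_numpy(), metric="cityblock")
    link = linkage(d, method="ward")
    assign = fcluster(link, t=n_clusters, criterion="maxclust")
    correspondence = None
    if labels is not None:
        y = np.asarray(labels)
        classes = np.unique(y)
        if len(classes) == n_clusters:
            from itertools import permutations
            best = 0.0
            for perm in permutations(range(1, n_clusters + 1)):
                mapping = dict(zip(perm, classes))
                acc = float(np.mean([mapping[a] == t for a, t in zip(assign, y)]))
                best = max(best, acc)
            correspondence = best
    pca = PCA()
    pca.fit(Z.to_numpy())
    loadings = pd.DataFrame(pca.components_.T, index=Z.columns,
                            columns=[f"PC{i+1}" for i in range(pca.n_components_)])
    return ExploreReport(cluster_assignments=assign,
                         correspondence=correspondence,
                         pca_variance_ratio=pca.explained_variance_ratio_,
                         pca_loadings=loadings, dropped_columns=dropped)
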