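"""Expression-trend clustering over developmental stages.

Replicate columns are averaged per stage, each gene's stage profile is
z-scored (the symmetric red/blue heatmap convention), and the z-scored
profiles of LRT-significant genes are clustered by k-means — k = 12 for a
fine partition, k = 5 for the representative trends.  Centroids over the
five canonical stages can be labelled by their best-correlated trend
archetype (early-only, early-pair, increasing, mid-peak, late-pair).
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

from .io_formats import StageDesign
from .simulate import ARCHETYPE_SHAPES

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterAssignment",
    "stage_mean_matrix",
    "row_zscore",
    "kmeans_trends",
    "match_trend_templates",
    "TrendKMeans",
    "TREND_TEMPLATES",
]


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD
    return (values - mean) / sd


#: Canonical 5-stage trend templates, z-scored; priority order breaks
#: correlation ties.
TREND_TEMPLATES: dict[str, np.ndarray] = {
    name.replace("_", "-"): _zscore_rows(np.asarray(shape, dtype=float)[None, :])[0]
    for name, shape in ARCHETYPE_SHAPES.items()
}


def stage_mean_matrix(normalized: pd.DataFrame, design: StageDesign) -> pd.DataFrame:
    """One column per stage: the arithmetic mean of its replicate columns."""
    labels = design.stage_labels(list(normalized.columns))
    cols = {}
    for stage in design.stages:
        members = labels == stage
        if not members.any():
            raise ValueError(f"stage {stage!r} has no samples in the matrix")
        cols[stage] = normalized.loc[:, members].mean(axis=1)
    out = pd.DataFrame(cols, index=normalized.index)
    out.attrs["provenance"] = "replicate-averaged"
    return out


def row_zscore(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each row to mean 0, population SD 1; drop constant rows.

    Constant rows carry no trend information and would divide by zero;
    they are excluded and logged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 stages to z-score a trend")
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.info("row_zscore: dropping %d constant rows", int(constant.sum()))
    kept = matrix.loc[~constant]
    out = pd.DataFrame(_zscore_rows(kept.to_numpy(dtype=float)),
                       index=kept.index, columns=kept.columns)
    out.attrs["provenance"] = "replicate-averaged, row-z-scored"
    out.attrs["dropped_constant"] = list(matrix.index[constant])
    return out


@dataclasses.dataclass
class ClusterAssignment:
    """k-means partition of gene trends.

    Cluster ids run 1..k and are relabelled by descending cluster size so
    the numbering is stable across runs with the same seed.
    """

    labels: pd.Series              # gene -> cluster id (1-based)
    centroids: pd.DataFrame        # cluster id x stage
    k: int
    seed: int
    inertia: float

    def members(self, cluster_id: int) -> set[str]:
        return set(self.labels.index[self.labels == cluster_id])


def kmeans_trends(
    matrix: pd.DataFrame,
    k: int,
    seed: int = 42,
    n_init: int = 25,
) -> ClusterAssignment:
    """Best-of-``n_init`` Lloyd's k-means on z-scored trend rows.

    Euclidean distance, k-means++ initialisation, deterministic under
    ``seed``.  Cluster ids are relabelled by descending size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds the {len(matrix)} rows available")
    km = KMeans(n_clusters=k, n_init=n_init, init="k-means++",
                algorithm="lloyd", random_state=seed)
    raw = km.fit_predict(matrix.to_numpy(dtype=float))

    sizes = np.bincount(raw, minlength=k)
    # descending size; ties broken by centroid values so the numbering does
    # not depend on gene order
    order = sorted(range(k),
                   key=lambda c: (-sizes[c],
                                  tuple(np.round(km.cluster_centers_[c], 9))))
    order = np.asarray(order)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = pd.Series(relabel[raw], index=matrix.index, name="cluster_id")

    centroids = pd.DataFrame(km.cluster_centers_[order],
                             index=pd.RangeIndex(1, k + 1, name="cluster_id"),
                             columns=matrix.columns)
    return ClusterAssignment(labels=labels, centroids=centroids, k=k,
                             seed=seed, inertia=float(km.inertia_))


def match_trend_templates(assignment: ClusterAssignment) -> dict[int, tuple[str, float]]:
    """Label each centroid by its maximally correlated canonical template.

    Returns ``{cluster_id: (template_name, pearson_r)}``.  Centroids that
    do not span the five canonical stages, or have zero variance, are
    labelled ``"custom"`` with correlation NaN.  Ties go to the earlier
    template in priority order, with a warning.
    """
    out: dict[int, tuple[str, float]] = {}
    n_stages = assignment.centroids.shape[1]
    for cid, centroid in assignment.centroids.iterrows():
        v = centroid.to_numpy(dtype=float)
        if n_stages != 5 or v.std() == 0:
            if v.std() == 0:
                warnings.warn(f"cluster {cid}: degenerate (constant) centroid")
            out[cid] = ("custom", float("nan"))
            continue
        best_name, best_r = None, -np.inf
        tied = []
        for name, template in TREND_TEMPLATES.items():
            r = float(np.corrcoef(v, template)[0, 1])
            if r > best_r + 1e-12:
                best_name, best_r = name, r
                tied = [name]
            elif abs(r - best_r) <= 1e-12:
                tied.append(name)
        if len(tied) > 1:
            warnings.warn(f"cluster {cid}: template tie {tied}; "
                          f"keeping {best_name!r} by priority order")
        out[cid] = (best_name, best_r)
    return out


class TrendKMeans(ClusterMixin, BaseEstimator):
    """Stage-trend k-means as a scikit-learn clusterer.

    ``fit(X)`` takes a genes x stages matrix of replicate-averaged
    normalized expression (rows = genes, the objects being clustered),
    z-scores each row, and runs best-of-``n_init`` k-means.  Constant rows
    are dropped before clustering; their ids are kept in
    ``dropped_constant_``.
    """

    def __init__(self, k: int = 5, seed: int = 42, n_init: int = 25,
                 zscore: bool = True):
        self.k = k
        self.seed = seed
        self.n_init = n_init
        self.zscore = zscore

    def fit(self, X, y=None):
        frame = pd.DataFrame(X)
        if self.zscore:
            frame = row_zscore(frame)
            self.dropped_constant_ = frame.attrs.get("dropped_constant", [])
        else:
            self.dropped_constant_ = []
        assignment = kmeans_trends(frame, self.k, seed=self.seed,
                                   n_init=self.n_init)
        self.assignment_ = assignment
        self.labels_ = assignment.labels.to_numpy()
        self.cluster_centers_ = assignment.centroids.to_numpy()
        self.inertia_ = assignment.inertia
        if frame.shape[1] == 5:
            self.trend_labels_ = match_trend_templates(assignment)
        return self
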