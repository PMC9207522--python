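"""Normalization and negative-binomial differential expression testing.

The model follows the classic count-based DE recipe: median-of-ratios size
factors, a per-gene NB GLM with log link and fixed gene-wise dispersion, a
likelihood-ratio test of the stage factor against an intercept-only model
(chi-square, df = stages - 1), pairwise Wald tests per stage pair, and
Benjamini-Hochberg adjustment over all tested genes with no independent
filtering.

Dispersion is estimated by a pooled within-stage method-of-moments
(``alpha = max(floor, (var - mean) / mean^2)``) rather than an
empirical-Bayes shrinkage fit; no fold-change shrinkage is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .glm import fit_nb_glm
from .io_formats import StageDesign, _order_stages

__all__ = [
    "NormalizationError",
    "filter_low_count_genes",
    "estimate_size_factors",
    "normalize",
    "estimate_dispersion",
    "lrt_stage_test",
    "wald_pairwise",
    "bh_adjust",
    "MedianOfRatiosNormalizer",
    "NegativeBinomialDE",
]

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8
LFC_CAP = 30.0

RESULT_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "stat",
                  "pvalue", "padj", "contrast", "flag"]


class NormalizationError(ValueError):
    pass


def filter_low_count_genes(counts: pd.DataFrame, min_total: int = 6) -> pd.DataFrame:
    """Drop genes whose raw-count sum over all samples is below ``min_total``.

    The default removes genes with a total strictly less than 6, applied
    before normalization; gene order is preserved.
    """
    keep = counts.sum(axis=1) >= min_total
    return counts.loc[keep]


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample j, ``sf_j = median_i (count_ij / geomean_i)`` over the
    reference genes i that have strictly positive counts in every sample
    (genes with any zero cannot contribute a finite log geometric mean).
    """
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise NormalizationError(
            "no gene has positive counts in all samples; cannot form "
            "geometric means — filter samples or supply size factors"
        )
    logs = np.log(values[reference])
    log_geomean = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample column by its size factor."""
    sf = size_factors.reindex(counts.columns)
    if sf.isna().any():
        raise NormalizationError("size factors missing for some samples")
    return counts / sf


def estimate_dispersion(
    normalized: pd.DataFrame,
    design: StageDesign,
    *,
    floor: float = DISPERSION_FLOOR,
    smooth: bool = True,
    n_bins: int = 20,
) -> pd.Series:
    """Pooled within-stage method-of-moments dispersion per gene.

    ``alpha = max(floor, (v - m) / m^2)`` where ``v`` pools the within-stage
    sample variances (weights n_k - 1) and ``m`` is the gene's mean
    normalized count.  Requires at least one stage with >= 2 replicates.

    With few replicates the raw per-gene estimate is very noisy and its
    underestimates make the downstream tests anti-conservative, so by
    default (``smooth=True``) each gene's estimate is floored at a
    mean-dispersion trend: the median raw estimate within log-mean bins.
    ``smooth=False`` returns the raw per-gene values.
    """
    labels = design.stage_labels(list(normalized.columns))
    var_num = np.zeros(len(normalized))
    dof = 0
    for stage in design.stages:
        cols = labels == stage
        n_k = int(cols.sum())
        if n_k >= 2:
            var_num += normalized.loc[:, cols].var(axis=1, ddof=1).to_numpy() * (n_k - 1)
            dof += n_k - 1
    if dof == 0:
        raise ValueError(
            "no stage has replicates; supply gene-wise dispersions explicitly"
        )
    v = var_num / dof
    m = normalized.mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m > 0, (v - m) / np.square(m), 0.0)
    alpha = np.maximum(alpha, floor)
    method = "pooled-within-stage-MoM"
    if smooth and len(alpha) >= 2:
        positive = m > 0
        bins = min(n_bins, max(1, int(positive.sum()) // 50))
        trend = np.full(len(alpha), np.median(alpha[positive]) if positive.any()
                        else floor)
        if bins >= 2 and positive.sum() >= 2 * bins:
            binned = pd.qcut(np.log(m[positive]), bins, duplicates="drop")
            med = pd.Series(alpha[positive]).groupby(binned, observed=True
                                                     ).transform("median")
            trend[positive] = med.to_numpy()
        alpha = np.maximum(alpha, trend)
        method += "+trend-floor"
    out = pd.Series(alpha, index=normalized.index, name="alpha")
    out.attrs["method"] = method
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up over all finite entries, aligned to input.

    NaN entries (untested/unconverged genes) are passed through and do not
    count towards m.  No independent filtering is applied.
    """
    p = np.asarray(pvalues, dtype=float)
    finite = np.isfinite(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if finite.any():
        out[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return out


def _ordered_samples(counts: pd.DataFrame, design: StageDesign,
                     stages: tuple[str, ...]) -> list[str]:
    labels = design.stage_labels(list(counts.columns))
    return [s for s, g in zip(counts.columns, labels) if g in set(stages)]


def _base_mean(normalized: pd.DataFrame) -> pd.Series:
    return normalized.mean(axis=1).rename("baseMean")


def lrt_stage_test(
    counts: pd.DataFrame,
    design: StageDesign,
    size_factors: pd.Series,
    dispersions: pd.Series,
) -> pd.DataFrame:
    """Likelihood-ratio test of the stage factor against the intercept.

    Per gene, an NB GLM with one coefficient per stage (full model) is
    compared with an intercept-only model (reduced); ``stat = 2 (ll_full -
    ll_reduced)`` is referred to chi-square with df = #stages - 1.  BH
    adjustment runs over all converged genes.
    """
    samples = list(counts.columns)
    labels = design.stage_labels(samples)
    y = counts.to_numpy(dtype=float)
    sf = size_factors.reindex(samples).to_numpy()
    offset = np.log(sf)
    alpha = dispersions.reindex(counts.index).to_numpy()

    X_full = np.stack([(labels == g).astype(float) for g in design.stages], axis=1)
    X_red = np.ones((len(samples), 1))
    full = fit_nb_glm(y, X_full, alpha, offset)
    red = fit_nb_glm(y, X_red, alpha, offset)

    stat = np.maximum(2.0 * (full.loglik_kernel - red.loglik_kernel), 0.0)
    df = len(design.stages) - 1
    ok = full.converged & red.converged
    pvalue = np.where(ok, stats.chi2.sf(stat, df), np.nan)

    res = pd.DataFrame(index=counts.index)
    res["baseMean"] = _base_mean(normalize(counts, size_factors))
    res["log2FoldChange"] = np.nan
    res["lfcSE"] = np.nan
    res["stat"] = stat
    res["pvalue"] = pvalue
    res["padj"] = bh_adjust(pvalue)
    res["contrast"] = "LRT"
    res["flag"] = np.where(ok, "", "no_convergence")
    return res[RESULT_COLUMNS]


def wald_pairwise(
    counts: pd.DataFrame,
    design: StageDesign,
    size_factors: pd.Series,
    dispersions: pd.Series,
    stage_a: str,
    stage_b: str,
) -> pd.DataFrame:
    """Wald test of stage B versus stage A.

    The NB GLM is fitted on the two stages' samples only;
    ``log2FoldChange`` is the B-vs-A coefficient on the log2 scale and
    ``stat`` the coefficient over its standard error (two-sided normal p).
    BH adjustment is per contrast.  baseMean remains the mean of normalized
    counts over *all* samples, so it is identical across contrasts.
    """
    for g in (stage_a, stage_b):
        if g not in design.stages:
            raise ValueError(f"unknown stage {g!r}")
    sub = _ordered_samples(counts, design, (stage_a, stage_b))
    labels = design.stage_labels(sub)
    y = counts[sub].to_numpy(dtype=float)
    sf = size_factors.reindex(sub).to_numpy()
    alpha = dispersions.reindex(counts.index).to_numpy()

    X = np.stack([np.ones(len(sub)), (labels == stage_b).astype(float)], axis=1)
    fit = fit_nb_glm(y, X, alpha, np.log(sf))

    lfc = fit.beta[:, 1] / LN2
    lfc_se = fit.se[:, 1] / LN2
    capped = np.abs(lfc) > LFC_CAP
    lfc = np.clip(lfc, -LFC_CAP, LFC_CAP)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(lfc_se > 0, fit.beta[:, 1] / fit.se[:, 1], np.nan)
    pvalue = np.where(fit.converged, 2.0 * stats.norm.sf(np.abs(z)), np.nan)

    flag = np.where(fit.converged, "", "no_convergence")
    flag = np.where(capped & fit.converged, "lfc_capped", flag)

    res = pd.DataFrame(index=counts.index)
    res["baseMean"] = _base_mean(normalize(counts, size_factors))
    res["log2FoldChange"] = lfc
    res["lfcSE"] = lfc_se
    res["stat"] = z
    res["pvalue"] = pvalue
    res["padj"] = bh_adjust(pvalue)
    res["contrast"] = f"{stage_b}_vs_{stage_a}"
    res["flag"] = flag
    return res[RESULT_COLUMNS]


# ---------------------------------------------------------------------------
# estimator layer


class MedianOfRatiosNormalizer(TransformerMixin, BaseEstimator):
    """Size-factor normalization as a scikit-learn transformer.

    Follows the sklearn orientation: rows are samples, columns are genes.
    ``fit`` estimates one positive size factor per sample by the
    median-of-ratios rule; ``transform`` divides each row by its factor.
    """

    def fit(self, X, y=None):
        frame = pd.DataFrame(X)
        self.size_factors_ = estimate_size_factors(frame.T).to_numpy()
        self.n_features_in_ = frame.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "size_factors_")
        frame = pd.DataFrame(X)
        if frame.shape[0] != len(self.size_factors_):
            raise ValueError("transform expects the same samples as fit")
        out = frame.to_numpy(dtype=float) / self.size_factors_[:, None]
        if isinstance(X, pd.DataFrame):
            return pd.DataFrame(out, index=X.index, columns=X.columns)
        return out


class NegativeBinomialDE(BaseEstimator):
    """Stage-factor NB differential expression as an estimator.

    ``fit(X, y)`` takes a samples x genes raw count matrix ``X`` and a
    stage label per sample ``y``; it filters low-count genes, estimates
    size factors and pooled method-of-moments dispersions, and fits the
    stage GLM.  Results are exposed through :meth:`lrt_results` and
    :meth:`wald_results`.

    Parameters
    ----------
    min_total : drop genes whose raw-count sum is below this (default 6).
    alpha_floor : lower bound for the dispersion estimate.
    stage_order : explicit stage ordering; defaults to developmental order
        for the canonical oocyte labels, else first appearance in ``y``.
    """

    def __init__(self, min_total: int = 6, alpha_floor: float = DISPERSION_FLOOR,
                 stage_order: tuple[str, ...] | None = None):
        self.min_total = min_total
        self.alpha_floor = alpha_floor
        self.stage_order = stage_order

    def fit(self, X, y):
        frame = pd.DataFrame(X)
        labels = np.asarray(y, dtype=object)
        if len(labels) != frame.shape[0]:
            raise ValueError("one stage label per sample (row) is required")
        counts = frame.T  # genes x samples internally
        counts.columns = [str(c) for c in counts.columns]
        order = (tuple(self.stage_order) if self.stage_order is not None
                 else _order_stages(list(labels)))
        design = StageDesign(
            stages=order,
            sample_to_stage=dict(zip(counts.columns, (str(l) for l in labels))),
        )
        counts = filter_low_count_genes(counts, self.min_total)
        sf = estimate_size_factors(counts)
        normalized = normalize(counts, sf)
        self.design_ = design
        self.counts_ = counts
        self.size_factors_ = sf
        self.normalized_ = normalized
        self.dispersions_ = estimate_dispersion(normalized, design,
                                                floor=self.alpha_floor)
        self.base_mean_ = _base_mean(normalized)
        self.n_features_in_ = frame.shape[1]
        return self

    def lrt_results(self) -> pd.DataFrame:
        check_is_fitted(self, "design_")
        return lrt_stage_test(self.counts_, self.design_, self.size_factors_,
                              self.dispersions_)

    def wald_results(self, stage_a: str, stage_b: str) -> pd.DataFrame:
        check_is_fitted(self, "design_")
        return wald_pairwise(self.counts_, self.design_, self.size_factors_,
                             self.dispersions_, stage_a, stage_b)

    def all_pairwise(self, stages: tuple[str, ...] | None = None
                     ) -> dict[str, pd.DataFrame]:
        """Wald results for every ordered-by-development stage pair."""
        check_is_fitted(self, "design_")
        stages = stages or self.design_.stages
        out = {}
        for i, a in enumerate(stages):
            for b in stages[i + 1:]:
                res = self.wald_results(a, b)
                out[str(res["contrast"].iloc[0])] = res
        return out
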