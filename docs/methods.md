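# Methods

## Count model and tests

Counts are modelled per gene as negative binomial with the
mean–dispersion parameterization Var(K) = μ + αμ² and a log-link GLM,
log μᵢⱼ = xⱼᵀβᵢ + log sⱼ, where sⱼ are per-sample size factors. Size
factors are median-of-ratios: for each sample, the median over reference
genes (genes positive in every sample) of the count divided by the
gene's geometric mean. They are defined up to a global constant fixed by
the geometric-mean convention; only their ratios are identified, which is
what the normalization uses.

Two tests are run on each gene. The likelihood-ratio test compares a
model with one free mean per stage against an intercept-only model;
2·Δloglik is referred to χ² with df = stages − 1. Pairwise Wald tests
fit the two stages' samples with an intercept-plus-indicator design; the
indicator coefficient on the log₂ scale is the reported fold change, and
coefficient/SE is referred to the standard normal. P-values are
BH-adjusted over all converged genes, separately per test, with no
independent filtering. The LRT stat uses only the μ-dependent
log-likelihood terms — the y-and-α-only terms cancel exactly between
nested models with shared dispersion, which keeps the statistic clean at
the dispersion floor.

### Fitting

Both models are fitted by iteratively reweighted least squares with the
gene-wise dispersion held fixed, vectorised across genes (one shared
design matrix, batched weighted normal equations). Convergence is
max|Δβ| < 1e-8 with at most 100 iterations; non-converged genes are
flagged, given undefined p, and excluded from the BH denominator.
Coefficients are clamped at ±45 on the natural-log scale to keep
all-zero groups finite; reported |log₂FC| is additionally capped at 30
with an `lfc_capped` flag. A tiny ridge (1e-10) stabilises the normal
equations when a group's fitted mean collapses toward zero. With
dispersion at the floor the fit coincides with a Poisson GLM; in the
two-group case its MLE is the closed-form ratio of offset-weighted group
means, which the test suite checks to 1e-6, alongside a direct
coefficient/SE/likelihood comparison against statsmodels' NB GLM at
fixed α.

### Dispersion

The per-gene estimate is pooled within-stage method-of-moments:
α̂ = max(floor, (v − m)/m²) with v the replicate variance pooled across
stages (weights nₖ − 1) and m the mean normalized count; the floor is
1e-8. With two replicates per stage this raw estimate has ~5 degrees of
freedom, and its underestimates make the LRT strongly anti-conservative
(null rejection at 5% was ≈0.17 in simulation). The default therefore
floors each gene's estimate at a mean–dispersion trend — the median raw
estimate within up to 20 log-mean quantile bins — which brings the null
rejection rate to ≈0.05–0.06 while never *lowering* any gene's
dispersion (conservative by construction). `smooth=False` restores the
raw estimator. No empirical-Bayes shrinkage toward the trend and no
fold-change shrinkage are performed; fold changes are unshrunk MLEs.

Residual small-sample liberality of the χ² approximation at 2
replicates/stage remains and is the reason calibration is stated as a
band (nominal to ~2× nominal) rather than a point.

## DEG rules

Comparisons follow the stated wording exactly: baseMean > 5 and
padj < 0.05 strict, |log₂FC| strictly above the baseMean-dependent
cutoff 5/√baseMean + 0.6 (strictly decreasing, asymptote 0.6); the
alternative simple rule takes fold ≥ 2 inclusive and FDR < 0.05 strict.
For the LRT gene list, which has no single fold change, the fold
criterion uses each gene's largest-magnitude pairwise log₂FC when
pairwise results are available and is otherwise skipped (recorded in the
rule provenance) — both paths are exposed because the source procedure is
ambiguous on this point. Every constructed DEG set re-tests its members
against the admitting predicate as a self-audit.

## Trend clustering

Normalized counts are replicate-averaged per stage, and each gene's
stage profile is z-scored to mean 0, population SD 1 (the symmetric
heatmap convention; constant rows are dropped and logged). Averaging
precedes z-scoring — the alternative order is not distinguishable from
the published description and this one matches the displayed
duplicate-averaged heatmaps. K-means uses Euclidean distance, k-means++
initialisation, best of 25 runs, fixed seed (default 42); cluster ids
are relabelled by descending size with a centroid-value tie-break so the
numbering is independent of gene order. k is a user parameter (defaults
12 and 5); no selection rule is imposed. Five canonical templates
(early-only, early-pair, increasing, mid-peak, late-pair) label 5-stage
centroids by Pearson correlation, ties broken by template priority with
a warning.

## Ortholog collapse

The partition (one_to_one / one_to_many / unannotated) is recomputed
from the mapping itself: a zebrafish gene is one_to_many iff ≥ 2
zebrafish genes share its human ortholog. The directionality test
quantifies over DEGs only: paralogs absent from the DEG set cannot veto
inclusion; groups larger than two follow the same all-same-sign rule.
Zero-direction members (possible only after fold capping) are excluded
with a warning as unresolved. Collapse is per contrast. Effective
coverage in percent of annotated genes is
100·(f₁:₁ + c·f₁:ₘ) with c the concordant fraction among human genes
reached by ≥ 2 DEGs. Note the published class counts this arithmetic is
checked against are internally inconsistent by 39 genes (9722 + 5361 ≠
15122); the reconstruction uses the two class counts as given, and the
resulting percentages differ from the printed ones by < 0.3 points.

## Enrichment

One-sided hypergeometric upper-tail ORA (P[X ≥ k]) per term, BH across
tested terms. The default background is the human universe reachable
from the tested genes — the least biased choice when no explicit
universe is supplied. Terms are intersected with the background before
testing; depletion is not assessed.

## Synthetic data

The generator emulates the study layout: 5 stages in duplicate, NB
counts with Var = μ + αμ², log-uniform baselines (default 10–500),
log-uniform dispersions (default 0.01–0.2), log-uniform size factors in
[0.7, 1.4], and five trend archetypes encoded as stage-multiplier shapes
(multiplier = fold^shape, so max/min ratio equals the drawn fold,
default 4–8). The orthology generator assigns 40% of genes no human
ortholog, places 35.4% of annotated genes in paralog pairs, and plants
sign agreement among both-DEG pairs with probability 0.8. One seed
drives a hierarchical seed sequence; each sub-generator has its own
child stream.

What the generator does **not** emulate: GC/length biases, count
outliers, correlated genes, batch effects, somatic-cell contamination,
or realistic effect-size distributions (the published clusters give no
quantitative effect sizes, so the fold ranges are conventions). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under the assumed model, not performance on real libraries.

## Problem sizes and determinism

The calibration and recovery studies run at 5,000 null genes (type-I
error), 4,000 genes with 30% planted 8-fold trends at μ ≥ 50 and
α ≤ 0.05 (recovery), 1,500 genes at 16-fold separation (trend ARI), and
12,000 genes (concordance measurement) — sizes at which the binomial
error of the measured rates is a few per mille and a full run takes
seconds. All pipeline outputs are byte-identical given the same inputs
and seed; the run manifest records config, thresholds, input checksums
and per-stage record counts.

## Known limitations

- Dispersion estimation is deliberately simpler than empirical-Bayes
  shrinkage; per-gene power at 2 replicates is correspondingly lower,
  and the trend floor can over-disperse genes whose true α is far below
  their expression stratum's median.
- No outlier handling (Cook's distance) and no multi-factor designs.
- The Wald p uses the normal reference, liberal at extreme means with
  tiny replicate numbers (the same band caveat as the LRT applies).
- The collapse assumes the orthology table is correct; it has no notion
  of confidence per assignment, and "associated"-only orthologs are
  treated as unannotated.
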