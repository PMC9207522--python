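"""End-to-end orchestration: filter -> normalize -> LRT + pairwise Wald ->
DEG filters -> trend clustering -> ortholog collapse -> enrichment.

The symmetry-breaking stage (SymBrk) participates in the LRT and the trend
clustering but is excluded from the pairwise comparisons by default, so a
5-stage design yields C(4,2) = 6 pairwise contrasts.  Everything is
deterministic given the configured seed; the manifest records inputs,
thresholds, and per-stage record counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import deg_filter, diffexpr, enrich, io_formats, ortho_map, trend_cluster
from .io_formats import StageDesign

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "run_analysis"]


@dataclasses.dataclass
class PipelineConfig:
    counts_path: str | None = None
    design_path: str | None = None
    orthology_path: str | None = None
    gene_sets_path: str | None = None
    out_dir: str = "results"
    exclude_stages: tuple[str, ...] = ("Symbrk",)   # from pairwise analysis only
    min_total: int = 6
    padj_cut: float = 0.05
    basemean_min: float = 5.0
    fold_rule: str = "basemean_dependent"           # or "simple"
    fold_min: float = 2.0
    k_values: tuple[int, ...] = (12, 5)
    cluster_seed: int = 42
    n_init: int = 25
    enrich_fdr: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.padj_cut < 1):
            raise ValueError("padj_cut must be in (0, 1)")
        if self.fold_rule not in ("basemean_dependent", "simple"):
            raise ValueError("fold_rule must be 'basemean_dependent' or 'simple'")
        if self.min_total < 0 or self.basemean_min < 0:
            raise ValueError("thresholds must be non-negative")


@dataclasses.dataclass
class PipelineResult:
    lrt: pd.DataFrame
    pairwise: dict[str, pd.DataFrame]
    lrt_degs: deg_filter.DEGSet
    pairwise_degs: dict[str, deg_filter.DEGSet]
    clusterings: dict[int, trend_cluster.ClusterAssignment]
    trend_labels: dict[int, tuple[str, float]] | None
    collapsed: dict[str, ortho_map.CollapsedDEGSet]
    coverage: ortho_map.CoverageStats | None
    enrichment: dict[str, pd.DataFrame]
    manifest: dict


def _max_magnitude_lfc(pairwise: dict[str, pd.DataFrame]) -> pd.Series | None:
    """Per gene, the largest-|.| pairwise log2FoldChange across contrasts."""
    if not pairwise:
        return None
    frames = [r["log2FoldChange"] for r in pairwise.values()]
    stacked = pd.concat(frames, axis=1)
    idx = stacked.abs().to_numpy().argmax(axis=1)
    vals = stacked.to_numpy()[np.arange(len(stacked)), idx]
    return pd.Series(vals, index=stacked.index, name="log2FoldChange")


def run_analysis(
    counts: pd.DataFrame,
    design: StageDesign,
    config: PipelineConfig,
    orthology: pd.DataFrame | None = None,
    gene_sets: dict | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}}
    n_in = len(counts)

    counts = diffexpr.filter_low_count_genes(counts, config.min_total)
    manifest["stages"]["filter"] = {
        "genes_in": n_in, "genes_filtered_out": n_in - len(counts),
        "genes_tested": len(counts),
    }
    sf = diffexpr.estimate_size_factors(counts)
    normalized = diffexpr.normalize(counts, sf)
    dispersions = diffexpr.estimate_dispersion(normalized, design)
    manifest["stages"]["normalize"] = {
        "size_factors": {k: round(float(v), 6) for k, v in sf.items()}
    }

    lrt = diffexpr.lrt_stage_test(counts, design, sf, dispersions)

    pairwise_stages = tuple(g for g in design.stages
                            if g not in set(config.exclude_stages))
    pairwise: dict[str, pd.DataFrame] = {}
    for i, a in enumerate(pairwise_stages):
        for b in pairwise_stages[i + 1:]:
            res = diffexpr.wald_pairwise(counts, design, sf, dispersions, a, b)
            pairwise[str(res["contrast"].iloc[0])] = res
    manifest["stages"]["tests"] = {
        "n_pairwise_contrasts": len(pairwise),
        "pairwise_stages": list(pairwise_stages),
    }

    if config.fold_rule == "simple":
        pw_degs = {c: deg_filter.call_degs_simple(r, config.fold_min,
                                                  config.padj_cut)
                   for c, r in pairwise.items()}
    else:
        pw_degs = {c: deg_filter.call_degs(r, config.padj_cut,
                                           config.basemean_min)
                   for c, r in pairwise.items()}
    lrt_degs = deg_filter.call_degs(lrt, config.padj_cut, config.basemean_min,
                                    lfc_lookup=_max_magnitude_lfc(pairwise))
    manifest["stages"]["degs"] = {
        "lrt": len(lrt_degs), **{c: len(d) for c, d in pw_degs.items()}
    }

    # trend clustering over the LRT-significant genes, all stages included
    clusterings: dict[int, trend_cluster.ClusterAssignment] = {}
    trend_labels = None
    cluster_genes = [g for g in counts.index if g in lrt_degs.genes]
    if cluster_genes:
        stage_means = trend_cluster.stage_mean_matrix(
            normalized.loc[cluster_genes], design)
        z = trend_cluster.row_zscore(stage_means)
        for k in config.k_values:
            if k <= len(z):
                clusterings[k] = trend_cluster.kmeans_trends(
                    z, k, seed=config.cluster_seed, n_init=config.n_init)
        if 5 in clusterings and len(design.stages) == 5:
            trend_labels = trend_cluster.match_trend_templates(clusterings[5])
    manifest["stages"]["clustering"] = {
        "n_clustered": len(cluster_genes),
        "k_values": [k for k in clusterings],
    }

    collapsed: dict[str, ortho_map.CollapsedDEGSet] = {}
    coverage = None
    enrichment: dict[str, pd.DataFrame] = {}
    if orthology is not None:
        for contrast, degs in pw_degs.items():
            collapsed[contrast] = ortho_map.directionality_collapse(degs,
                                                                    orthology)
        coverage = ortho_map.coverage_statistics(
            orthology,
            collapsed=next(iter(collapsed.values())) if collapsed else None,
        )
        if gene_sets:
            # background: the human universe reachable from tested genes
            tested = orthology.loc[orthology.index.isin(counts.index),
                                   "human_gene"].dropna()
            background = set(tested)
            for contrast, coll in collapsed.items():
                query = set(coll.included) & background
                sig, full = enrich.hypergeometric_ora(
                    query, gene_sets, background, config.enrich_fdr)
                enrichment[contrast] = full
        manifest["stages"]["collapse"] = {
            c: {"included": len(s.included), "conflicts": len(s.conflicts),
                "unresolved": len(s.unresolved)}
            for c, s in collapsed.items()
        }
    return PipelineResult(lrt=lrt, pairwise=pairwise, lrt_degs=lrt_degs,
                          pairwise_degs=pw_degs, clusterings=clusterings,
                          trend_labels=trend_labels, collapsed=collapsed,
                          coverage=coverage, enrichment=enrichment,
                          manifest=manifest)


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Read the configured inputs, run the analysis, write all artifacts."""
    if not config.counts_path or not config.design_path:
        raise ValueError("counts_path and design_path are required")
    counts, design = io_formats.read_count_matrix(config.counts_path,
                                                  config.design_path)
    orthology = (io_formats.read_orthology_table(config.orthology_path)
                 if config.orthology_path else None)
    gene_sets = (io_formats.read_gmt(config.gene_sets_path)
                 if config.gene_sets_path else None)

    result = run_analysis(counts, design, config, orthology, gene_sets)
    result.manifest["inputs"] = {
        p: _sha256(getattr(config, p))
        for p in ("counts_path", "design_path", "orthology_path",
                  "gene_sets_path")
        if getattr(config, p)
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.lrt.to_csv(out / "lrt_results.tsv", sep="\t",
                      index_label="gene_id", float_format="%.6g")
    for contrast, res in result.pairwise.items():
        res.to_csv(out / f"wald_{contrast}.tsv", sep="\t",
                   index_label="gene_id", float_format="%.6g")

    deg_rows = []
    for degset in [result.lrt_degs, *result.pairwise_degs.values()]:
        t = degset.table.reset_index(names="gene_id")
        t.insert(1, "contrast", degset.contrast)
        deg_rows.append(t)
    deg_table = (pd.concat(deg_rows, ignore_index=True) if deg_rows
                 else pd.DataFrame())

    cluster_table = None
    if result.clusterings:
        parts = []
        for k, assignment in result.clusterings.items():
            part = assignment.labels.reset_index()
            part.columns = ["gene_id", "cluster_id"]
            part.insert(1, "k", k)
            if k == 5 and result.trend_labels:
                part["trend_label"] = part["cluster_id"].map(
                    {cid: lab for cid, (lab, _) in result.trend_labels.items()})
            parts.append(part)
            assignment.centroids.to_csv(out / f"centroids_k{k}.tsv", sep="\t",
                                        float_format="%.6g")
        cluster_table = pd.concat(parts, ignore_index=True)

    first_collapsed = (next(iter(result.collapsed.values()))
                       if result.collapsed else None)
    io_formats.write_results(deg_table, cluster_table, first_collapsed, out,
                             metadata=result.manifest)
    for contrast, full in result.enrichment.items():
        full.to_csv(out / f"enrichment_{contrast}.tsv", sep="\t", index=False,
                    float_format="%.6g")
    return result
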