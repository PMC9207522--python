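"""Significance filters that turn test results into DEG sets.

Two rules are used in different places of the analysis and both are
exposed:

* the baseMean-dependent rule — ``baseMean > 5``, ``padj < 0.05`` and
  ``|log2FoldChange| > 5 / sqrt(baseMean) + 0.6``, which demands a larger
  fold from lowly expressed genes and relaxes towards 0.6 (a 1.5-fold) for
  highly expressed ones;
* the simple rule — fold change of at least 2 (inclusive) and FDR < 0.05
  (strict), used for the pairwise Venn comparison.

Comparisons follow the stated wording exactly: ``baseMean > 5``,
``padj < cut`` and the threshold comparison are strict; "at least 2" is
inclusive.
"""

from __future__ import annotations

import dataclasses
from itertools import product
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEGSet",
    "fold_change_threshold",
    "call_degs",
    "call_degs_simple",
    "pairwise_unique_partition",
]


def fold_change_threshold(base_mean):
    """The baseMean-dependent |log2FoldChange| cutoff: ``5 / sqrt(baseMean) + 0.6``.

    Strictly decreasing in baseMean with asymptote 0.6.  Accepts scalars or
    arrays; requires baseMean > 0.
    """
    bm = np.asarray(base_mean, dtype=float)
    if np.any(bm <= 0):
        raise ValueError("baseMean must be positive")
    out = 5.0 / np.sqrt(bm) + 0.6
    return float(out) if np.isscalar(base_mean) or bm.ndim == 0 else out


@dataclasses.dataclass
class DEGSet:
    """Genes admitted by a filter rule for one contrast.

    ``table`` is indexed by gene id with columns ``direction`` (+1 up, -1
    down, 0 for direction-less LRT membership), ``baseMean``,
    ``log2FoldChange``, ``padj`` and ``rule`` (filter provenance).
    """

    contrast: str
    table: pd.DataFrame
    rule: str

    @property
    def genes(self) -> set[str]:
        return set(self.table.index)

    @property
    def directions(self) -> pd.Series:
        return self.table["direction"]

    @property
    def signed(self) -> bool:
        # pairwise sets carry directions; LRT membership does not
        return self.contrast != "LRT"

    def __len__(self) -> int:
        return len(self.table)


def _require_columns(results: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise KeyError(f"result table missing columns: {missing}")


def _build_set(results: pd.DataFrame, member: np.ndarray, contrast: str,
               rule: str, directed: bool) -> DEGSet:
    sub = results.loc[member, ["baseMean", "log2FoldChange", "padj"]].copy()
    if directed:
        sub.insert(0, "direction",
                   np.sign(sub["log2FoldChange"]).astype(int))
    else:
        sub.insert(0, "direction", 0)
    sub["rule"] = rule
    return DEGSet(contrast=contrast, table=sub, rule=rule)


def call_degs(
    results: pd.DataFrame,
    padj_cut: float = 0.05,
    basemean_min: float = 5.0,
    *,
    lfc_lookup: pd.Series | None = None,
) -> DEGSet:
    """Apply the baseMean-dependent rule to a result table.

    A gene is a member iff ``baseMean > basemean_min``, ``padj < padj_cut``
    and ``|log2FoldChange| > fold_change_threshold(baseMean)``.  For an LRT
    table (no per-gene fold change) the fold criterion uses
    ``lfc_lookup`` — typically each gene's largest-magnitude pairwise
    log2FoldChange — or is skipped entirely (recorded in ``rule``) when no
    lookup is supplied.
    """
    _require_columns(results, ["baseMean", "padj", "log2FoldChange", "contrast"])
    contrast = str(results["contrast"].iloc[0]) if len(results) else "empty"
    is_lrt = contrast == "LRT"

    lfc = results["log2FoldChange"].copy()
    rule = "basemean_dependent"
    fold_applied = True
    if is_lrt:
        if lfc_lookup is not None:
            lfc = lfc_lookup.reindex(results.index)
        else:
            fold_applied = False
            rule = "basemean_dependent(fold_criterion_skipped)"

    bm = results["baseMean"].to_numpy(dtype=float)
    padj = results["padj"].to_numpy(dtype=float)
    member = (bm > basemean_min) & (np.where(np.isfinite(padj), padj, 1.0) < padj_cut)
    if fold_applied:
        with np.errstate(invalid="ignore", divide="ignore"):
            thr = np.where(bm > 0, 5.0 / np.sqrt(np.maximum(bm, 1e-300)) + 0.6,
                           np.inf)
        abs_lfc = np.abs(lfc.to_numpy(dtype=float))
        member &= np.where(np.isfinite(abs_lfc), abs_lfc, -np.inf) > thr
    directed = fold_applied and not is_lrt
    out = _build_set(results, member, contrast, rule, directed)
    if is_lrt and fold_applied:
        out.table["log2FoldChange"] = lfc.reindex(out.table.index)
    _audit(out, padj_cut, basemean_min)
    return out


def call_degs_simple(
    results: pd.DataFrame,
    fold_min: float = 2.0,
    fdr_cut: float = 0.05,
) -> DEGSet:
    """Apply the simple rule: fold change of at least ``fold_min`` and
    FDR strictly below ``fdr_cut``.  Pairwise results only."""
    _require_columns(results, ["log2FoldChange", "padj", "contrast"])
    if len(results) and str(results["contrast"].iloc[0]) == "LRT":
        raise ValueError("the simple fold rule applies to pairwise contrasts only")
    contrast = str(results["contrast"].iloc[0]) if len(results) else "empty"
    lfc = results["log2FoldChange"].to_numpy(dtype=float)
    padj = results["padj"].to_numpy(dtype=float)
    member = (np.where(np.isfinite(np.abs(lfc)), np.abs(lfc), -np.inf)
              >= np.log2(fold_min))
    member &= np.where(np.isfinite(padj), padj, 1.0) < fdr_cut
    return _build_set(results, member, contrast, f"fold{fold_min:g}_fdr{fdr_cut:g}",
                      directed=True)


def _audit(degset: DEGSet, padj_cut: float, basemean_min: float) -> None:
    """Self-check: every member re-tests TRUE against its admitting rule."""
    t = degset.table
    if len(t) == 0:
        return
    assert (t["baseMean"] > basemean_min).all()
    assert (t["padj"] < padj_cut).all()
    if "skipped" not in degset.rule:
        thr = fold_change_threshold(t["baseMean"].to_numpy())
        assert (np.abs(t["log2FoldChange"].to_numpy()) > thr).all()


def pairwise_unique_partition(degsets: Iterable[DEGSet]) -> dict[tuple[bool, ...], int]:
    """Counts of genes per membership signature across DEG sets (Venn regions).

    The signature is a tuple of booleans in the order the sets are given;
    the all-False region is reported as 0 and the remaining counts sum to
    the size of the union.
    """
    sets = [d.genes for d in degsets]
    if len(sets) < 2:
        raise ValueError("need at least 2 DEG sets")
    universe = set().union(*sets)
    out: dict[tuple[bool, ...], int] = {
        sig: 0 for sig in product([False, True], repeat=len(sets))
    }
    for gene in universe:
        sig = tuple(gene in s for s in sets)
        out[sig] += 1
    return out
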