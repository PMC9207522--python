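"""Hypergeometric over-representation analysis of human DEG sets.

For a query of size ``n`` drawn from a background universe of size ``N``
and a term with ``K`` background members, the enrichment p-value is the
upper tail ``P[X >= k]`` of Hypergeometric(N, K, n) at the observed
overlap ``k``.  Terms are BH-adjusted across all tested terms; enrichment
only (no depletion) is assessed.  The background defaults to the universe
the collapse produced, i.e. the tested genes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["hypergeometric_ora"]

RESULT_COLUMNS = ["term", "description", "overlap", "term_size", "query_size",
                  "background_size", "pvalue", "fdr", "overlap_genes"]


def hypergeometric_ora(
    query: Iterable[str],
    gene_sets: Mapping[str, tuple[str, frozenset[str]]],
    background: Iterable[str],
    fdr_cut: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test each gene set for over-representation in the query.

    Parameters
    ----------
    query : human gene set of interest; must be a subset of ``background``.
    gene_sets : term -> (description, members), e.g. from
        :func:`oostager.io_formats.read_gmt`.  Each term is intersected
        with the background before testing; terms with no background
        member are skipped.
    background : the gene universe.
    fdr_cut : FDR threshold for the significant table.

    Returns
    -------
    significant : rows with ``fdr < fdr_cut``, sorted by p-value.
    full : all tested terms (same columns).
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(
            f"{len(stray)} query genes are not in the background: "
            f"{sorted(stray)[:10]}"
        )
    N, n = len(background), len(query)
    rows = []
    for term, (desc, members) in gene_sets.items():
        in_bg = members & background
        if not in_bg:
            continue
        K = len(in_bg)
        overlap = in_bg & query
        k = len(overlap)
        # upper tail P[X >= k]; k = 0 gives p = 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "description": desc, "overlap": k,
                     "term_size": K, "query_size": n, "background_size": N,
                     "pvalue": min(p, 1.0),
                     "overlap_genes": ",".join(sorted(overlap))})
    full = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "fdr"])
    full["fdr"] = bh_adjust(full["pvalue"]) if len(full) else []
    full = full[RESULT_COLUMNS].sort_values(
        ["pvalue", "term"], kind="stable").reset_index(drop=True)
    significant = full[full["fdr"] < fdr_cut].reset_index(drop=True)
    return significant, full
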