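"""Zebrafish -> human ortholog conversion with the directionality test.

Because of the teleost genome duplication, one human gene is often the
ortholog of several zebrafish paralogs (typically two).  A naive 1:1-only
conversion discards those genes.  Instead:

* 1:1 orthologs pass straight through to the human name;
* for a human gene with several zebrafish orthologs, only the zebrafish
  genes present in the DEG set are considered — if all of them changed in
  the same direction the human gene is included with that direction, while
  any opposite significant change omits the gene and records a conflict;
* unannotated zebrafish DEGs are kept as unresolved records.

Coverage arithmetic: with a fraction ``f11`` of annotated genes in 1:1
orthology, ``f1m`` in one-to-many, and a concordant fraction ``c`` among
both-DEG paralog groups, the effective coverage of annotated genes is
``f11 + c * f1m``.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import defaultdict

import numpy as np
import pandas as pd

from .deg_filter import DEGSet

__all__ = [
    "CollapsedDEGSet",
    "CoverageStats",
    "partition_orthology",
    "directionality_collapse",
    "coverage_statistics",
]

RELATIONS = ("one_to_one", "one_to_many", "unannotated")


def partition_orthology(table: pd.DataFrame) -> tuple[pd.Series, dict[str, int]]:
    """Label every zebrafish gene one_to_one / one_to_many / unannotated.

    The partition is a function of the mapping alone: a gene is
    one_to_many iff at least two zebrafish genes share its human ortholog.
    Returns the per-gene labels and the counts per relation.
    """
    human = table["human_gene"]
    annotated = human.notna()
    shared = human.map(human.value_counts())
    relation = pd.Series(
        np.where(~annotated, "unannotated",
                 np.where(shared >= 2, "one_to_many", "one_to_one")),
        index=table.index, name="relation",
    )
    counts = {r: int((relation == r).sum()) for r in RELATIONS}
    return relation, counts


@dataclasses.dataclass
class CollapsedDEGSet:
    """Human-nomenclature DEG set plus conflict and unresolved records.

    Every zebrafish DEG lands in exactly one of: contributor to an
    included human gene, member of a conflict record, or unresolved
    (unannotated, or unsigned after fold-change capping).
    """

    contrast: str
    included: dict[str, tuple[int, tuple[str, ...]]]   # human -> (direction, zf genes)
    conflicts: dict[str, tuple[tuple[str, int], ...]]  # human -> ((zf, sign), ...)
    unresolved: tuple[tuple[str, str], ...]            # (zf gene, reason)

    def included_frame(self) -> pd.DataFrame:
        rows = [
            {"human_gene": h, "direction": d, "zf_contributors": ",".join(zfs),
             "contrast": self.contrast}
            for h, (d, zfs) in sorted(self.included.items())
        ]
        return pd.DataFrame(rows, columns=["human_gene", "direction",
                                           "zf_contributors", "contrast"])

    def conflict_frame(self) -> pd.DataFrame:
        rows = [
            {"human_gene": h,
             "zf_genes": ",".join(z for z, _ in members),
             "signs": ",".join(str(s) for _, s in members),
             "contrast": self.contrast}
            for h, members in sorted(self.conflicts.items())
        ]
        return pd.DataFrame(rows, columns=["human_gene", "zf_genes", "signs",
                                           "contrast"])

    def unresolved_frame(self) -> pd.DataFrame:
        rows = [{"zf_gene": z, "reason": r, "contrast": self.contrast}
                for z, r in self.unresolved]
        return pd.DataFrame(rows, columns=["zf_gene", "reason", "contrast"])

    def conservation_check(self, degs: DEGSet) -> bool:
        """|DEG set| == contributors + conflict members + unresolved."""
        n_contrib = sum(len(zfs) for _, zfs in self.included.values())
        n_conflict = sum(len(m) for m in self.conflicts.values())
        return n_contrib + n_conflict + len(self.unresolved) == len(degs)


def directionality_collapse(degs: DEGSet, table: pd.DataFrame) -> CollapsedDEGSet:
    """Collapse a signed zebrafish DEG set onto human nomenclature.

    The same-direction rule quantifies over DEGs only: a paralog that is
    not itself in the DEG set cannot veto its sibling.
    """
    if not degs.signed:
        raise ValueError(
            "directionality collapse needs a signed (pairwise) DEG set; "
            "LRT membership carries no direction"
        )
    human_of = table["human_gene"].to_dict()

    by_human: dict[str, list[tuple[str, int]]] = defaultdict(list)
    unresolved: list[tuple[str, str]] = []
    for zf in degs.table.index:
        sign = int(degs.table.at[zf, "direction"])
        human = human_of.get(zf)
        if human is None or (isinstance(human, float) and np.isnan(human)):
            unresolved.append((zf, "unannotated"))
        elif sign == 0:
            warnings.warn(f"{zf}: unsigned DEG (zero log2FoldChange) excluded "
                          "from the collapse")
            unresolved.append((zf, "unsigned"))
        else:
            by_human[human].append((zf, sign))

    included: dict[str, tuple[int, tuple[str, ...]]] = {}
    conflicts: dict[str, tuple[tuple[str, int], ...]] = {}
    for human, members in by_human.items():
        signs = {s for _, s in members}
        if len(signs) == 1:
            included[human] = (signs.pop(), tuple(z for z, _ in members))
        else:
            conflicts[human] = tuple(members)
    return CollapsedDEGSet(contrast=degs.contrast, included=included,
                           conflicts=conflicts, unresolved=tuple(unresolved))


@dataclasses.dataclass
class CoverageStats:
    """Orthology coverage arithmetic over annotated zebrafish genes."""

    n_annotated: int
    n_one_to_one: int
    n_one_to_many: int
    fraction_one_to_one: float
    fraction_one_to_many: float
    concordant_fraction: float
    effective_coverage: float   # percent of annotated genes usable
    residual_fraction: float    # percent requiring manual investigation

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def coverage_statistics(
    table: pd.DataFrame,
    degs: DEGSet | None = None,
    collapsed: CollapsedDEGSet | None = None,
    *,
    concordant_fraction: float | None = None,
) -> CoverageStats:
    """Coverage fractions of the ortholog conversion.

    ``concordant_fraction`` is measured from ``collapsed`` — among human
    genes reached by two or more zebrafish DEGs, the fraction whose DEGs
    agreed in sign — unless given explicitly.  ``effective_coverage`` (in
    percent of annotated genes) is ``fraction_one_to_one +
    concordant_fraction * fraction_one_to_many``.
    """
    _, counts = partition_orthology(table)
    n_ann = counts["one_to_one"] + counts["one_to_many"]
    if n_ann == 0:
        return CoverageStats(0, 0, 0, float("nan"), float("nan"),
                             float("nan"), float("nan"), float("nan"))
    f11 = counts["one_to_one"] / n_ann
    f1m = counts["one_to_many"] / n_ann

    if concordant_fraction is None and collapsed is not None:
        multi_ok = sum(1 for _, zfs in collapsed.included.values() if len(zfs) >= 2)
        n_multi = multi_ok + len(collapsed.conflicts)
        concordant_fraction = multi_ok / n_multi if n_multi else float("nan")
    c = float("nan") if concordant_fraction is None else float(concordant_fraction)

    effective = 100.0 * (f11 + c * f1m) if np.isfinite(c) else float("nan")
    residual = 100.0 - effective if np.isfinite(effective) else float("nan")
    return CoverageStats(
        n_annotated=n_ann,
        n_one_to_one=counts["one_to_one"],
        n_one_to_many=counts["one_to_many"],
        fraction_one_to_one=f11,
        fraction_one_to_many=f1m,
        concordant_fraction=c,
        effective_coverage=effective,
        residual_fraction=residual,
    )
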