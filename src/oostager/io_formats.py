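"""Tabular I/O for the pipeline: count matrices, stage designs, orthology
tables, GMT gene-set collections, and result writers.

All files are tab-separated UTF-8 with a header row.  Gene identifiers are
opaque strings; no namespace manipulation is performed unless explicitly
requested (``strip_versions``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StageDesign",
    "FormatError",
    "ConsistencyError",
    "CANONICAL_STAGES",
    "read_count_matrix",
    "read_design",
    "read_orthology_table",
    "read_gmt",
    "write_results",
    "write_count_matrix",
    "write_design",
    "write_orthology_table",
]

#: Developmental order of the oocyte stage groups: symmetry breaking,
#: nuclear cleft, mature Balbiani body, cortical alveolus, vitellogenesis.
CANONICAL_STAGES = ("Symbrk", "Nuc", "MatBb", "StageII", "StageIII")


class FormatError(ValueError):
    """A file violates a structural invariant (duplicates, bad values)."""


class ConsistencyError(ValueError):
    """Two inputs that must agree (counts vs design) do not."""


@dataclasses.dataclass(frozen=True)
class StageDesign:
    """Ordered stage labels plus the sample -> stage assignment.

    Stage order is preserved as given; when the canonical oocyte stage
    labels are used they are expected in developmental order
    (Symbrk < Nuc < MatBb < StageII < StageIII).
    """

    stages: tuple[str, ...]
    sample_to_stage: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(self.stages) < 2:
            raise FormatError("a design needs at least 2 stages")
        if len(set(self.stages)) != len(self.stages):
            raise FormatError("duplicate stage labels in design")
        extra = set(self.sample_to_stage.values()) - set(self.stages)
        if extra:
            raise ConsistencyError(f"samples map to unknown stages: {sorted(extra)}")
        for stage in self.stages:
            if stage not in self.sample_to_stage.values():
                raise FormatError(f"stage {stage!r} has no samples")

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.sample_to_stage)

    def samples_of(self, stage: str) -> tuple[str, ...]:
        return tuple(s for s, g in self.sample_to_stage.items() if g == stage)

    def stage_labels(self, samples: Sequence[str]) -> np.ndarray:
        """Stage label per sample, in the given sample order."""
        missing = [s for s in samples if s not in self.sample_to_stage]
        if missing:
            raise ConsistencyError(f"samples absent from design: {missing}")
        return np.asarray([self.sample_to_stage[s] for s in samples])

    def subset(self, keep_stages: Sequence[str]) -> "StageDesign":
        keep = [s for s in self.stages if s in set(keep_stages)]
        mapping = {s: g for s, g in self.sample_to_stage.items() if g in set(keep)}
        return StageDesign(stages=tuple(keep), sample_to_stage=mapping)


def _order_stages(stages: Sequence[str]) -> tuple[str, ...]:
    # Canonical oocyte labels get developmental order; anything else keeps
    # first-appearance order from the file.
    uniq = list(dict.fromkeys(stages))
    if set(uniq) <= set(CANONICAL_STAGES):
        return tuple(s for s in CANONICAL_STAGES if s in uniq)
    return tuple(uniq)


def read_design(path: str | Path) -> StageDesign:
    """Read a design TSV with columns ``sample_id`` and ``stage``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "stage"):
        if col not in df.columns:
            raise FormatError(f"design file missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in design: {dups}")
    mapping = dict(zip(df["sample_id"], df["stage"]))
    return StageDesign(stages=_order_stages(df["stage"]), sample_to_stage=mapping)


def read_count_matrix(
    path: str | Path,
    design_path: str | Path,
    *,
    strip_versions: bool = False,
) -> tuple[pd.DataFrame, StageDesign]:
    """Read a gene x sample raw count TSV plus its stage design.

    The count file has gene ids in the first column and one column per
    sample.  Counts must be non-negative integers.  Every sample in the
    design must appear in the count header and vice versa.

    Returns
    -------
    counts : DataFrame (genes x samples, integer)
    design : StageDesign
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids: {dups}")
    if strip_versions:
        df.index = df.index.str.replace(r"\.\d+$", "", regex=True)
        if df.index.duplicated().any():
            raise FormatError("version stripping produced duplicate gene ids")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise FormatError("non-numeric count values")
    if np.any(values < 0):
        raise FormatError("negative counts are not allowed")
    if not np.allclose(values, np.round(values)):
        raise FormatError("counts must be integers (raw counts, not normalized)")
    counts = df.astype(np.int64)

    design = read_design(design_path)
    in_counts = set(counts.columns)
    in_design = set(design.samples)
    if in_design - in_counts:
        raise ConsistencyError(
            f"design samples missing from count matrix: {sorted(in_design - in_counts)}"
        )
    if in_counts - in_design:
        raise ConsistencyError(
            f"count-matrix samples missing from design: {sorted(in_counts - in_design)}"
        )
    return counts, design


def read_orthology_table(path: str | Path) -> pd.DataFrame:
    """Read a zebrafish -> human orthology TSV.

    Columns ``zf_gene`` and ``human_gene`` are required; ``human_gene`` may
    be empty (unannotated).  Several zebrafish genes may share one human
    gene (one-to-many orthology, the teleost-duplication case).  An optional
    ``relation`` column in the file is advisory only; the partition is
    always recomputed from the mapping itself.

    Returns a DataFrame indexed by ``zf_gene`` with a ``human_gene`` column
    where unannotated entries are ``None``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("zf_gene", "human_gene"):
        if col not in df.columns:
            raise FormatError(f"orthology file missing column {col!r}")
    df = df.replace({"human_gene": {"": None}})
    grouped = df.groupby("zf_gene")["human_gene"].nunique(dropna=False)
    conflicts = grouped[grouped > 1].index.tolist()
    if conflicts:
        raise FormatError(
            f"zebrafish genes with conflicting human assignments: {conflicts}"
        )
    out = df.drop_duplicates("zf_gene").set_index("zf_gene")[["human_gene"]]
    out["human_gene"] = out["human_gene"].where(out["human_gene"].notna(), None)
    return out


def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read a GMT gene-set collection: term, description, members per line."""
    collection: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT line with fewer than 3 fields: {line!r}")
        term, desc, members = fields[0], fields[1], [g for g in fields[2:] if g]
        if term in collection:
            raise FormatError(f"duplicate GMT term {term!r}")
        if not members:
            raise FormatError(f"empty GMT term {term!r}")
        collection[term] = (desc, frozenset(members))
    return collection


# ---------------------------------------------------------------------------
# writers

_FLOAT_FMT = "%.6g"


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def write_design(design: StageDesign, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": list(design.samples),
         "stage": [design.sample_to_stage[s] for s in design.samples]}
    ).to_csv(path, sep="\t", index=False)


def write_orthology_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["human_gene"] = out["human_gene"].fillna("")
    out.to_csv(path, sep="\t", index_label="zf_gene")


def write_results(
    deg_table: pd.DataFrame | None,
    cluster_table: pd.DataFrame | None,
    collapsed_set,
    out_dir: str | Path,
    *,
    metadata: Mapping | None = None,
) -> list[Path]:
    """Write result TSVs plus a run-metadata JSON with deterministic layout.

    ``collapsed_set`` is a :class:`oostager.ortho_map.CollapsedDEGSet` (or
    None).  Column order is fixed and floats use a fixed precision so that
    identical inputs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if deg_table is not None:
        p = out_dir / "degs.tsv"
        deg_table.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(p)
    if cluster_table is not None:
        p = out_dir / "clusters.tsv"
        cluster_table.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
        written.append(p)
    if collapsed_set is not None:
        for name, frame in (
            ("collapsed.tsv", collapsed_set.included_frame()),
            ("conflicts.tsv", collapsed_set.conflict_frame()),
            ("unresolved.tsv", collapsed_set.unresolved_frame()),
        ):
            p = out_dir / name
            frame.to_csv(p, sep="\t", index=False, float_format=_FLOAT_FMT)
            written.append(p)
    meta_path = out_dir / "run_metadata.json"
    meta_path.write_text(json.dumps(dict(metadata or {}), indent=2, sort_keys=True) + "\n")
    written.append(meta_path)
    return written
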