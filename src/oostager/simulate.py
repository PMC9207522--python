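"""Synthetic data with the statistical structure the analysis assumes.

Counts are negative-binomial with the variance function ``var = mu + alpha
mu^2`` (the DESeq2-family parameterization), per-sample size factors emulate
library-size variation, and non-null genes follow one of five stage-trend
archetypes (early-only, early-pair, increasing, mid-peak, late-pair) that
mirror the major expression trends of developing oocyte stage groups.  The
orthology generator plants one-to-many zebrafish paralog pairs with a
tunable directional-concordance fraction among both-DEG pairs.

Every generator is fully deterministic given ``SimConfig.seed``; each
sub-generator draws from its own child stream of a hierarchical seed
sequence so the pieces are independently reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import CANONICAL_STAGES, StageDesign

__all__ = [
    "SimConfig",
    "ARCHETYPE_SHAPES",
    "generate_truth",
    "generate_design",
    "generate_counts",
    "generate_orthology",
    "truth_signs",
]

#: Unit shapes (0 = low plateau, 1 = high plateau) over the five canonical
#: stages.  A gene's stage multiplier is ``effect_fold ** shape``, so the
#: low plateau has multiplier 1 and max/min ratio equals the drawn fold.
ARCHETYPE_SHAPES: dict[str, tuple[float, ...]] = {
    "early_only": (1.0, 0.0, 0.0, 0.0, 0.0),
    "early_pair": (1.0, 1.0, 0.0, 0.0, 0.0),
    "increasing": (0.0, 0.25, 0.5, 0.75, 1.0),
    "mid_peak": (0.0, 1.0, 1.0, 0.0, 0.0),
    "late_pair": (0.0, 0.0, 0.0, 1.0, 1.0),
}

ARCHETYPE_NAMES = ("flat",) + tuple(ARCHETYPE_SHAPES)


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study layout: 5 stages sequenced in duplicate,
    ~80% directional concordance among both-DEG paralog pairs, 35.4% of
    annotated zebrafish genes in one-to-many orthology groups and 40% of
    all genes without a curated human ortholog.
    """

    n_genes: int = 2000
    n_stages: int = 5
    n_reps: int = 2
    fraction_null: float = 0.5
    effect_fold: tuple[float, float] = (4.0, 8.0)
    baseline_mean: tuple[float, float] = (10.0, 500.0)
    dispersion: tuple[float, float] = (0.01, 0.2)
    size_factor_range: tuple[float, float] = (0.7, 1.4)
    paralog_fraction: float = 0.354
    unannotated_fraction: float = 0.40
    concordance: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_stages < 2 or self.n_reps < 1:
            raise ValueError("need >= 2 stages and >= 1 replicate")
        for name in ("fraction_null", "paralog_fraction", "unannotated_fraction",
                     "concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect_fold[0] < 1.0 or self.effect_fold[1] < self.effect_fold[0]:
            raise ValueError("effect_fold must be an increasing range >= 1")
        if self.dispersion[0] < 0:
            raise ValueError("dispersion must be >= 0")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def rng(self, stream: int) -> np.random.Generator:
        """Child RNG for a named sub-generator (0 truth, 1 counts, 2 orthology)."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(stream,))
        )


def _stage_names(n_stages: int) -> list[str]:
    if n_stages == 5:
        return list(CANONICAL_STAGES)
    return [f"stage{i + 1}" for i in range(n_stages)]


def _archetype_shape(name: str, n_stages: int) -> np.ndarray:
    shape5 = np.asarray(ARCHETYPE_SHAPES[name])
    if n_stages == 5:
        return shape5
    # resample the canonical shape onto the requested number of stages
    return np.interp(np.linspace(0, 4, n_stages), np.arange(5), shape5)


def generate_design(config: SimConfig) -> StageDesign:
    """Replicated stage design: ``n_reps`` samples per stage."""
    stages = _stage_names(config.n_stages)
    mapping = {
        f"{stage}_r{r + 1}": stage for stage in stages for r in range(config.n_reps)
    }
    return StageDesign(stages=tuple(stages), sample_to_stage=mapping)


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Per-gene ground truth: archetype, stage multipliers, baseline, dispersion.

    Returns a DataFrame indexed by gene id with columns ``archetype``,
    ``baseline``, ``alpha`` and ``mult_<stage>`` for every stage.  Flat
    (null) genes have all multipliers equal to 1; non-null genes have a
    max/min multiplier ratio equal to their drawn effect fold.
    """
    rng = config.rng(0)
    n = config.n_genes
    genes = [f"zf{i:05d}" for i in range(n)]
    stages = _stage_names(config.n_stages)

    is_null = rng.random(n) < config.fraction_null
    arch_idx = rng.integers(0, len(ARCHETYPE_SHAPES), size=n)
    archetype = np.where(is_null, "flat",
                         np.asarray(list(ARCHETYPE_SHAPES))[arch_idx])

    lo, hi = config.effect_fold
    fold = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    mult = np.ones((n, config.n_stages))
    for name in ARCHETYPE_SHAPES:
        mask = archetype == name
        if mask.any():
            shape = _archetype_shape(name, config.n_stages)
            mult[mask] = fold[mask, None] ** shape[None, :]

    blo, bhi = config.baseline_mean
    baseline = np.exp(rng.uniform(np.log(blo), np.log(bhi), size=n))
    alo, ahi = config.dispersion
    if alo == ahi:
        alpha = np.full(n, alo)
    elif alo == 0.0:
        alpha = rng.uniform(alo, ahi, size=n)
    else:
        alpha = np.exp(rng.uniform(np.log(alo), np.log(ahi), size=n))

    truth = pd.DataFrame({"archetype": archetype, "baseline": baseline,
                          "alpha": alpha}, index=pd.Index(genes, name="gene_id"))
    for j, stage in enumerate(stages):
        truth[f"mult_{stage}"] = mult[:, j]
    return truth


def generate_counts(
    truth: pd.DataFrame,
    design: StageDesign,
    config: SimConfig,
    *,
    size_factors: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """NB counts for every gene x sample, plus the true size factors used.

    ``count_ij ~ NB(mean = baseline_i * mult_i,stage(j) * sf_j, alpha_i)``
    with ``var = mu + alpha mu^2``; ``alpha = 0`` degenerates to Poisson.
    """
    rng = config.rng(1)
    samples = list(design.samples)
    if size_factors is None:
        lo, hi = config.size_factor_range
        size_factors = np.exp(rng.uniform(np.log(lo), np.log(hi), len(samples)))
    sf = pd.Series(np.asarray(size_factors, dtype=float), index=samples,
                   name="size_factor")

    mult_cols = [f"mult_{design.sample_to_stage[s]}" for s in samples]
    mu = (truth["baseline"].to_numpy()[:, None]
          * truth[mult_cols].to_numpy()
          * sf.to_numpy()[None, :])
    alpha = truth["alpha"].to_numpy()[:, None]

    counts = np.empty(mu.shape, dtype=np.int64)
    poisson = np.broadcast_to(alpha, mu.shape) == 0.0
    if poisson.any():
        counts[poisson] = rng.poisson(mu[poisson])
    if (~poisson).any():
        size = 1.0 / alpha
        size = np.broadcast_to(size, mu.shape)
        p = size / (size + mu)
        counts[~poisson] = rng.negative_binomial(size[~poisson], p[~poisson])
    return (
        pd.DataFrame(counts, index=truth.index, columns=samples),
        sf,
    )


def truth_signs(truth: pd.DataFrame, stage_a: str, stage_b: str) -> pd.Series:
    """Planted DEG sign for the contrast B vs A: sign(mult_B - mult_A)."""
    diff = truth[f"mult_{stage_b}"] - truth[f"mult_{stage_a}"]
    return pd.Series(np.sign(diff).astype(int), index=truth.index, name="sign")


def generate_orthology(
    config: SimConfig,
    deg_truth: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Zebrafish -> human orthology table with planted paralog structure.

    ``deg_truth`` is a signed truth per zebrafish gene (+1 up, -1 down,
    0 not a DEG).  A ``paralog_fraction`` of annotated genes is placed in
    one-to-many groups of two; among pairs where both members are DEGs the
    signs agree with probability ``concordance``.  An
    ``unannotated_fraction`` of genes receives no human ortholog.

    Returns
    -------
    table : DataFrame indexed by zf_gene with column ``human_gene``
        (None when unannotated).
    pairs : DataFrame of planted pairs with columns ``human_gene``,
        ``zf_a``, ``zf_b``, ``both_deg``, ``concordant``.
    """
    rng = config.rng(2)
    genes = np.asarray(deg_truth.index)
    signs = deg_truth.to_numpy()

    n = len(genes)
    perm = rng.permutation(n)
    n_unann = int(round(config.unannotated_fraction * n))
    unannotated = set(genes[perm[:n_unann]])
    annotated_idx = perm[n_unann:]

    n_paired = int(round(config.paralog_fraction * len(annotated_idx)))
    n_pairs = n_paired // 2

    up = [i for i in annotated_idx if signs[i] > 0]
    down = [i for i in annotated_idx if signs[i] < 0]
    null = [i for i in annotated_idx if signs[i] == 0]
    for pool in (up, down, null):
        rng.shuffle(pool)

    pair_rows = []
    mapping: dict[str, str | None] = {}
    h = 0

    def _pop_pair() -> tuple[int, int, bool, bool] | None:
        """Draw one paralog pair, planting concordance among both-DEG pairs."""
        concordant = bool(rng.random() < config.concordance)
        if concordant:
            pools = [p for p in (up, down) if len(p) >= 2]
            if pools:
                pool = pools[int(rng.integers(len(pools)))]
                return pool.pop(), pool.pop(), True, True
        else:
            if up and down:
                return up.pop(), down.pop(), True, False
        # not enough signed genes left: fall back to pairs involving nulls
        rest = null + up + down
        if len(rest) < 2:
            return None
        a, b = rest[-1], rest[-2]
        for pool in (null, up, down):
            while a in pool:
                pool.remove(a)
            while b in pool:
                pool.remove(b)
        return a, b, False, bool(np.sign(signs[a]) == np.sign(signs[b]))

    for _ in range(n_pairs):
        drawn = _pop_pair()
        if drawn is None:
            break
        a, b, both_deg, concordant = drawn
        human = f"HS{h:05d}"
        h += 1
        mapping[genes[a]] = human
        mapping[genes[b]] = human
        pair_rows.append({"human_gene": human, "zf_a": genes[a],
                          "zf_b": genes[b], "both_deg": both_deg,
                          "concordant": concordant})

    for i in sorted(null + up + down):
        mapping[genes[i]] = f"HS{h:05d}"
        h += 1
    for g in unannotated:
        mapping[g] = None

    table = pd.DataFrame(
        {"human_gene": [mapping[g] for g in genes]},
        index=pd.Index(genes, name="zf_gene"),
    )
    pairs = pd.DataFrame(
        pair_rows, columns=["human_gene", "zf_a", "zf_b", "both_deg", "concordant"]
    )
    return table, pairs


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index_label="gene_id")
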