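"""Brain-expression statistics for gene sets.

Three analyses characterize a gene set (typically the genes of the expanding or
contracting families from the PGLS screen) in a human-style expression compendium:

* brain rank — per gene, the number of non-brain tissues whose expression
  exceeds the brain's; lower mean rank = more brain-biased. Significance by
  bootstrap: random gene sets of the same size drawn with replacement.
* temporal trajectory — mean log2(x+1) expression per developmental stage
  within a brain structure group (cortex / subcortex / cerebellum), summarized
  by an OLS slope over stages.
* sex-biased fold change — per gene, log2 female/male ratios across matched
  (region, stage) pairs, tested against zero by a one-sample Wilcoxon
  signed-rank test with BH correction across genes.

Replicate samples at the same (gene, tissue, stage, sex) are averaged before
any statistic.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import DegenerateInputError, ValidationError
from .pgls import bh_adjust

logger = logging.getLogger(__name__)

# Brain structure groups by region code (BrainSpan-style atlas labels).
DEFAULT_REGION_GROUPS: dict[str, tuple[str, ...]] = {
    "cortex": ("Ocx", "M1C-S1C", "STC", "MFC", "DFC", "OFC", "ITC", "HIP",
               "VFC", "PCx", "TCx", "A1C", "V1C", "M1C", "IPC", "S1C"),
    "subcortex": ("AMY", "MGE", "MD", "CGE", "DTH", "STR"),
    "cerebellum": ("URL", "CB", "CBC"),
}


def log2p1(x):
    """log2(x + 1): the transform applied to raw expression before averaging."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def average_replicates(expr: pd.DataFrame) -> pd.DataFrame:
    """Mean expression per (gene, tissue, stage, sex), keeping other columns' first value."""
    keys = ["gene", "tissue", "stage", "sex"]
    extra = [c for c in expr.columns if c not in keys + ["value"]]
    agg = {"value": "mean", **{c: "first" for c in extra}}
    return expr.groupby(keys, as_index=False, sort=False).agg(agg)


@dataclasses.dataclass
class RankResult:
    """Brain-rank summary for a gene set.

    ``mean_rank`` averages, over genes, the number of non-brain tissues whose
    expression exceeds the brain's (range 0..T-1 for T tissues). ``p_boot`` is
    the add-one bootstrap probability of a mean rank at least as brain-biased
    (as low) under random same-size gene sets; None until the bootstrap runs.
    """

    label: str
    mean_rank: float
    n_genes: int
    n_tissues: int
    per_gene_ranks: pd.Series
    p_boot: float | None = None
    boot_means: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "label": self.label,
            "mean_rank": self.mean_rank,
            "n_genes": self.n_genes,
            "n_tissues": self.n_tissues,
            "p_boot": self.p_boot,
        }])


def _gene_ranks(expr: pd.DataFrame, brain_label: str) -> tuple[pd.Series, int]:
    """Per-gene brain rank over all genes in the table with a brain value."""
    avg = average_replicates(expr)
    # collapse to one value per (gene, tissue): mean over stages/sexes
    per_tissue = avg.groupby(["gene", "tissue"], sort=False)["value"].mean().unstack()
    if brain_label not in per_tissue.columns:
        raise ValidationError(f"brain label {brain_label!r} not among tissues "
                              f"{list(per_tissue.columns)[:10]}...")
    n_tissues = per_tissue.shape[1]
    if n_tissues < 2:
        raise DegenerateInputError("need at least one non-brain tissue")
    brain = per_tissue[brain_label]
    others = per_tissue.drop(columns=[brain_label])
    usable = brain.notna() & others.notna().any(axis=1)
    dropped = int((~usable).sum())
    if dropped:
        logger.warning("brain_rank: %d genes without usable brain measurement excluded", dropped)
    # strict inequality: ties with the brain value do not increment the rank
    ranks = others.loc[usable].gt(brain.loc[usable], axis=0).sum(axis=1).astype(float)
    return ranks, n_tissues


def brain_rank(
    expr: pd.DataFrame,
    genes: Iterable[str],
    brain_label: str = "brain",
    label: str = "gene_set",
) -> RankResult:
    """Mean brain-expression rank of a gene set (no significance test).

    Rank of a gene = number of non-brain tissues with expression strictly
    greater than the brain's; depends only on the ordering of values, so any
    strictly increasing transform of expression leaves it unchanged.
    """
    ranks, n_tissues = _gene_ranks(expr, brain_label)
    gene_set = {str(g) for g in genes}
    present = ranks.index.intersection(gene_set)
    if len(present) == 0:
        raise ValidationError("no gene of the set has a usable brain measurement")
    if len(present) < len(gene_set):
        logger.warning("brain_rank: %d genes of the set missing from expression",
                       len(gene_set) - len(present))
    sub = ranks.loc[present]
    return RankResult(label, float(sub.mean()), len(sub), n_tissues, sub)


def bootstrap_rank_p(
    expr: pd.DataFrame,
    genes: Iterable[str],
    config: AnalysisConfig | None = None,
    seed: int | None = None,
    label: str = "gene_set",
) -> RankResult:
    """Brain rank with bootstrap significance.

    Background = every gene in the table with a brain value. Draws
    ``n_resamples`` gene sets of the same size with replacement, computes each
    set's mean rank, and returns p_boot = (1 + #{boot mean <= observed}) /
    (1 + n_resamples): the probability of brain bias at least as strong under
    random sets (low rank = brain-biased, hence lower tail).
    """
    if config is None:
        config = AnalysisConfig()
    ranks, n_tissues = _gene_ranks(expr, config.brain_label)
    if len(ranks) < 2:
        raise DegenerateInputError("bootstrap background needs >= 2 genes with brain values")
    res = brain_rank(expr, genes, config.brain_label, label)
    rng = np.random.default_rng(config.random_seed if seed is None else seed)
    pool = ranks.to_numpy()
    R, m = config.n_resamples, res.n_genes
    boot = np.empty(R)
    # chunked to bound memory at ~1e7 draws per block
    block = max(1, int(1e7 // max(m, 1)))
    for lo in range(0, R, block):
        hi = min(R, lo + block)
        draws = rng.choice(pool, size=(hi - lo, m), replace=True)
        boot[lo:hi] = draws.mean(axis=1)
    res.boot_means = boot
    res.p_boot = float((1.0 + np.sum(boot <= res.mean_rank)) / (1.0 + R))
    logger.info("bootstrap_rank_p[%s]: mean_rank=%.3f over %d genes, p_boot=%.4g (%d resamples)",
                label, res.mean_rank, m, res.p_boot, R)
    return res


def temporal_trajectory(
    expr: pd.DataFrame,
    genes: Iterable[str],
    group: str,
    region_groups: Mapping[str, Sequence[str]] | None = None,
    stage_axis: str = "ordinal",
) -> tuple[float, pd.DataFrame]:
    """Mean expression trajectory of a gene set across stages in one brain structure group.

    Per stage: average log2(x+1) expression over the group's regions, then over
    genes. The slope is the OLS slope of these stage means against the stage
    axis — the stage's ordinal position (default) or its ``stage_index`` column
    when ``stage_axis="numeric"``.

    Returns (slope, stage_means) where stage_means has columns stage,
    position, mean_expression, n_genes.
    """
    groups = dict(region_groups) if region_groups is not None else DEFAULT_REGION_GROUPS
    if group not in groups:
        raise ValidationError(f"unknown structure group {group!r}; expected {sorted(groups)}")
    if stage_axis not in ("ordinal", "numeric"):
        raise ValidationError("stage_axis must be 'ordinal' or 'numeric'")
    regions = set(groups[group])
    gene_set = {str(g) for g in genes}
    avg = average_replicates(expr)
    sub = avg[avg["tissue"].isin(regions) & avg["gene"].isin(gene_set)].copy()
    if sub.empty:
        raise ValidationError(f"no expression rows for group {group!r} and the gene set")
    sub["logval"] = log2p1(sub["value"])

    if stage_axis == "numeric":
        if "stage_index" not in sub.columns:
            raise ValidationError("stage_axis='numeric' requires a stage_index column")
        pos_of = sub.groupby("stage")["stage_index"].first()
    else:
        stages_in_order = list(dict.fromkeys(expr["stage"]))
        pos_of = pd.Series({s: i for i, s in enumerate(stages_in_order)})

    # per stage: mean over regions within gene, then over genes
    per_gene_stage = sub.groupby(["stage", "gene"], sort=False)["logval"].mean()
    stage_means = per_gene_stage.groupby(level="stage").mean()
    n_genes = per_gene_stage.groupby(level="stage").size()

    stages = [s for s in pos_of.index if s in stage_means.index]
    skipped = set(pos_of.index) - set(stages)
    if skipped:
        logger.info("temporal_trajectory[%s]: %d stages without data skipped", group, len(skipped))
    if len(stages) < 3:
        raise DegenerateInputError(f"group {group!r} has data in fewer than 3 stages")
    table = pd.DataFrame({
        "stage": stages,
        "position": [float(pos_of[s]) for s in stages],
        "mean_expression": [stage_means[s] for s in stages],
        "n_genes": [int(n_genes[s]) for s in stages],
    }).sort_values("position", ignore_index=True)
    slope = float(np.polyfit(table["position"], table["mean_expression"], 1)[0])
    logger.info("temporal_trajectory[%s]: slope=%.4g over %d stages", group, slope, len(stages))
    return slope, table


def sexbias_foldchange(
    expr: pd.DataFrame,
    genes: Iterable[str],
    phase: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Female-to-male log2 fold change per gene, one Wilcoxon test per gene.

    For each gene and each (tissue, stage) of the phase with both sexes
    measured: log2((female mean + 1) / (male mean + 1)), the pseudocount
    matching the log2(x+1) convention. The per-gene fold-change vector is
    tested against zero with a two-sided one-sample Wilcoxon signed-rank test
    (exact for <= 25 pairs, normal approximation with continuity correction
    above); p-values are BH-corrected across genes within the phase.

    Returns a DataFrame with columns gene, n_pairs, median_log2fc, p_wilcoxon,
    p_adj, all_zero.
    """
    if config is None:
        config = AnalysisConfig()
    if phase not in ("prenatal", "adult"):
        raise ValidationError("phase must be 'prenatal' or 'adult'")
    if "phase" not in expr.columns:
        raise ValidationError("expression table needs a 'phase' column for sex-bias analysis")
    gene_set = {str(g) for g in genes}
    avg = average_replicates(expr)
    sub = avg[(avg["phase"] == phase) & avg["gene"].isin(gene_set)
              & avg["sex"].isin(["female", "male"])]
    if sub.empty:
        raise ValidationError(f"no {phase} expression rows for the gene set")
    wide = sub.pivot_table(index=["gene", "tissue", "stage"], columns="sex",
                           values="value", aggfunc="mean")
    if not {"female", "male"}.issubset(wide.columns):
        raise ValidationError(f"phase {phase!r} lacks one of the sexes")
    wide = wide.dropna(subset=["female", "male"])

    rows = []
    for gene, grp in wide.groupby(level="gene", sort=True):
        lfc = np.log2((grp["female"].to_numpy() + 1.0) / (grp["male"].to_numpy() + 1.0))
        if lfc.size < 1:
            logger.info("sexbias_foldchange: gene %s has no matched pair, skipped", gene)
            continue
        all_zero = bool(np.all(lfc == 0))
        if all_zero:
            p = 1.0
        else:
            # auto: exact null for small n without zeros, else normal approximation
            # with continuity correction; Pratt's zero handling avoids hard errors
            p = float(stats.wilcoxon(lfc, zero_method="pratt", correction=True,
                                     alternative="two-sided", method="auto").pvalue)
        rows.append({
            "gene": gene,
            "n_pairs": int(lfc.size),
            "median_log2fc": float(np.median(lfc)),
            "p_wilcoxon": p,
            "all_zero": all_zero,
        })
    if not rows:
        raise DegenerateInputError(f"no gene had a matched (tissue, stage) pair in {phase}")
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p_wilcoxon"].to_numpy())
    logger.info("sexbias_foldchange[%s]: %d genes tested", phase, len(out))
    return out[["gene", "n_pairs", "median_log2fc", "p_wilcoxon", "p_adj", "all_zero"]]
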