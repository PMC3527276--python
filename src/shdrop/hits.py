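"""Synthetic-interaction hit calling and truth-based evaluation.

An shRNA is a hit when it is significantly depleted at least four-fold in
p53- cells while being at most two-fold depleted in p53+ cells — or not
significantly changed there at all.  The escape clause attaches to the p53+
condition only: the p53- side always requires significance, so an shRNA
whose p53+ point fold estimate exceeds two still passes if that change is
non-significant.  Categories mirror the volcano-plot colouring: genotype-
specific dropouts (red), shRNAs depleted in both lines (blue, generally
essential), and everything not depleted (black).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PipelineConfig, ShRNALibrary
from .simulate import ShRNAClass, SimTruth
from .stats import DepletionStat

# Caps applied only when encoding unbounded values for the volcano table.
LOG2_FOLD_CAP = 16.0
NEGLOG10_P_CAP = 300.0


class HitCategory(enum.Enum):
    P53MINUS_SPECIFIC = "P53MINUS_SPECIFIC"
    BOTH_DEPLETED = "BOTH_DEPLETED"
    NOT_DEPLETED = "NOT_DEPLETED"
    OTHER = "OTHER"


@dataclass(frozen=True)
class HitRecord:
    shrna_id: str
    gene_id: str
    is_hit: bool
    category: HitCategory


@dataclass(frozen=True)
class ScreenEvaluation:
    """Confusion matrix of hit calls against planted truth.

    Positive class: SYNTHETIC_P53MINUS shRNAs.  observed_fdr is
    FP / (TP + FP), defined as 0.0 when nothing was called.
    """

    true_positives: int
    false_positives: int
    false_negatives: int
    true_negatives: int

    @property
    def sensitivity(self) -> float:
        pos = self.true_positives + self.false_negatives
        return self.true_positives / pos if pos else float("nan")

    @property
    def observed_fdr(self) -> float:
        called = self.true_positives + self.false_positives
        return self.false_positives / called if called else 0.0


def _depleted(fold: float, p_adj: float, config: PipelineConfig) -> bool:
    return fold >= config.min_fold_p53minus and p_adj < config.alpha_adj


def classify_shrna(
    stat_minus: DepletionStat,
    stat_plus: DepletionStat,
    config: PipelineConfig,
    gene_id: str = "",
) -> HitRecord:
    """Apply the compound hit rule and volcano category to one shRNA."""
    if stat_minus.shrna_id != stat_plus.shrna_id:
        raise ValueError(
            f"mismatched shRNAs: {stat_minus.shrna_id!r} vs {stat_plus.shrna_id!r}"
        )
    depleted_minus = _depleted(stat_minus.fold_depletion, stat_minus.p_adj, config)
    depleted_plus = _depleted(stat_plus.fold_depletion, stat_plus.p_adj, config)
    quiet_plus = (
        stat_plus.fold_depletion <= config.max_fold_p53plus
        or stat_plus.p_adj >= config.alpha_adj
    )
    is_hit = depleted_minus and quiet_plus
    if is_hit:
        category = HitCategory.P53MINUS_SPECIFIC
    elif depleted_minus and depleted_plus:
        category = HitCategory.BOTH_DEPLETED
    elif not depleted_minus and not depleted_plus:
        category = HitCategory.NOT_DEPLETED
    else:
        category = HitCategory.OTHER
    return HitRecord(stat_minus.shrna_id, gene_id, is_hit, category)


def call_hits(
    stats_minus: pd.DataFrame,
    stats_plus: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Hit record per shRNA, merged with the stats of both genotypes.

    Indexed by shrna_id; columns is_hit, category, gene_id and the two
    genotypes' stat columns suffixed _minus / _plus.
    """
    if not stats_minus.index.equals(stats_plus.index):
        raise ValueError("genotype stats tables cover different shRNAs")
    config.validate()
    fold_m = stats_minus["fold_depletion"].to_numpy()
    padj_m = stats_minus["p_adj"].to_numpy()
    fold_p = stats_plus["fold_depletion"].to_numpy()
    padj_p = stats_plus["p_adj"].to_numpy()
    dep_m = (fold_m >= config.min_fold_p53minus) & (padj_m < config.alpha_adj)
    dep_p = (fold_p >= config.min_fold_p53minus) & (padj_p < config.alpha_adj)
    quiet_p = (fold_p <= config.max_fold_p53plus) | (padj_p >= config.alpha_adj)
    is_hit = dep_m & quiet_p
    category = np.where(
        is_hit,
        HitCategory.P53MINUS_SPECIFIC.value,
        np.where(
            dep_m & dep_p,
            HitCategory.BOTH_DEPLETED.value,
            np.where(
                ~dep_m & ~dep_p,
                HitCategory.NOT_DEPLETED.value,
                HitCategory.OTHER.value,
            ),
        ),
    )
    out = pd.DataFrame(
        {
            "gene_id": stats_minus["gene_id"],
            "is_hit": is_hit,
            "category": category,
        },
        index=stats_minus.index,
    )
    stat_cols = ["a", "c", "fold_depletion", "log2_fold", "odds_ratio", "ci_low", "ci_high", "p", "p_adj"]
    for col in stat_cols:
        out[f"{col}_minus"] = stats_minus[col]
    for col in stat_cols:
        out[f"{col}_plus"] = stats_plus[col]
    return out


def genes_from_hits(hit_records: pd.DataFrame, library: ShRNALibrary) -> pd.DataFrame:
    """Aggregate shRNA hits to genes (a gene needs >= 1 hit shRNA).

    Returns only flagged genes, sorted by hit-shRNA count (desc) then
    gene_id; columns gene_id, n_hit_shrnas, hit.
    """
    known_genes = set(library.gene_ids)
    unknown = set(hit_records["gene_id"]) - known_genes
    if unknown:
        raise ValueError(f"unknown gene_id in hit records: {sorted(unknown)[:5]}")
    hits = hit_records[hit_records["is_hit"]]
    counts = hits.groupby("gene_id").size().rename("n_hit_shrnas").reset_index()
    counts["hit"] = True
    counts = counts.sort_values(
        ["n_hit_shrnas", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return counts[["gene_id", "n_hit_shrnas", "hit"]]


def volcano_table(
    stats_minus: pd.DataFrame,
    stats_plus: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Volcano-plot coordinates and category per shRNA (p53- axis).

    Infinite log2 folds and zero p-values are capped at documented constants
    so the table stays plottable; the caps never feed back into hit calling.
    """
    records = call_hits(stats_minus, stats_plus, config)
    log2_fold = stats_minus["log2_fold"].clip(-LOG2_FOLD_CAP, LOG2_FOLD_CAP)
    with np.errstate(divide="ignore"):
        neglog_p = -np.log10(stats_minus["p_adj"].to_numpy())
    neglog_p = np.minimum(neglog_p, NEGLOG10_P_CAP)
    return pd.DataFrame(
        {
            "log2_fold_minus": log2_fold,
            "minus_log10_padj_minus": neglog_p,
            "category": records["category"],
        },
        index=stats_minus.index,
    )


def evaluate_against_truth(hit_records: pd.DataFrame, truth: SimTruth) -> ScreenEvaluation:
    """Score shRNA-level hit calls against planted classes."""
    truth_idx = truth.table.index
    if set(hit_records.index) != set(truth_idx):
        raise ValueError("hit records and truth cover different shRNAs")
    cls = truth.table.loc[hit_records.index, "class"]
    positive = (cls == ShRNAClass.SYNTHETIC_P53MINUS.value).to_numpy()
    called = hit_records["is_hit"].to_numpy()
    return ScreenEvaluation(
        true_positives=int((called & positive).sum()),
        false_positives=int((called & ~positive).sum()),
        false_negatives=int((~called & positive).sum()),
        true_negatives=int((~called & ~positive).sum()),
    )


def evaluate_genes_against_truth(
    gene_table: pd.DataFrame, truth: SimTruth
) -> ScreenEvaluation:
    """Score gene-level calls: positives are planted synthetic-lethal genes."""
    gene_classes = truth.gene_classes()
    called = set(gene_table["gene_id"])
    unknown = called - set(gene_classes.index)
    if unknown:
        raise ValueError(f"called genes absent from truth: {sorted(unknown)[:5]}")
    positive = set(gene_classes[gene_classes == ShRNAClass.SYNTHETIC_P53MINUS.value].index)
    all_genes = set(gene_classes.index)
    tp = len(called & positive)
    fp = len(called - positive)
    fn = len(positive - called)
    tn = len(all_genes - called - positive)
    return ScreenEvaluation(tp, fp, fn, tn)
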