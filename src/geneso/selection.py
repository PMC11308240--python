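"""Gene-subset selection driven by occlusion ranks, plus baseline selectors.

The primary strategy ranks genes by mean occlusion score (ties broken
lexicographically by gene id), builds reduced datasets from top fractions of
the ranking, retrains with repeated stratified five-fold cross-validation,
and keeps the subset with the highest validation accuracy.  Two published
comparison selectors are provided: a mean/std threshold filter and a
per-class median-difference top-k selector.  A depletion study measures the
accuracy cost of removing a gene set from a subset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._containers import DataError, NormalizedMatrix, OcclusionScoreTable
from .classifier import NetworkConfig, cross_validate

__all__ = [
    "GeneRanking",
    "SubsetResult",
    "rank_by_mean_occlusion",
    "select_top_fraction",
    "select_top_unique_per_class",
    "mostavi_select",
    "zhao_select",
    "optimize_subset",
    "depletion_study",
]


@dataclass
class GeneRanking:
    """Genes ordered by non-increasing mean occlusion score."""

    gene_ids: list[str]
    scores: np.ndarray
    tie_break: str = "lexicographic_gene_id"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if np.any(np.diff(self.scores) > 1e-15):
            raise DataError("ranking scores must be non-increasing")


@dataclass
class SubsetResult:
    strategy: str
    fraction: float | None
    gene_ids: list[str]
    fold_accuracies: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_accuracy: float = float("nan")
    median_accuracy: float = float("nan")


def rank_by_mean_occlusion(table: OcclusionScoreTable) -> GeneRanking:
    """Descending mean occlusion score; ties by gene id (stable, recorded)."""
    if not table.gene_ids:
        raise DataError("empty score table")
    means = table.mean_scores
    order = sorted(range(len(table.gene_ids)),
                   key=lambda i: (-means[i], table.gene_ids[i]))
    return GeneRanking([table.gene_ids[i] for i in order], means[order])


def select_top_fraction(ranking: GeneRanking, fraction: float) -> list[str]:
    """First ceil(fraction * N) genes of the ranking."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n = math.ceil(fraction * len(ranking.gene_ids))
    return ranking.gene_ids[:n]


def select_top_unique_per_class(table: OcclusionScoreTable,
                                fraction: float) -> list[str]:
    """Union over classes of each class's top-fraction genes by class score.

    Deduplicated; order is first appearance while iterating classes in
    canonical order, each class's list sorted by descending per-class score
    with gene-id tie-break.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if not table.gene_ids:
        raise DataError("empty score table")
    n = math.ceil(fraction * len(table.gene_ids))
    seen: dict[str, None] = {}
    for ci in range(len(table.class_labels)):
        col = table.scores[:, ci]
        order = sorted(range(len(table.gene_ids)),
                       key=lambda i: (-col[i], table.gene_ids[i]))
        for i in order[:n]:
            seen.setdefault(table.gene_ids[i], None)
    return list(seen)


def mostavi_select(m: NormalizedMatrix, threshold: float) -> list[str]:
    """Genes whose across-sample mean OR std exceeds ``threshold``.

    The published filter was applied to FPKM values; the criterion itself is
    unit-agnostic, so any normalization is accepted.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    mean = m.values.mean(axis=1)
    std = m.values.std(axis=1)
    keep = (mean > threshold) | (std > threshold)
    return [g for g, k in zip(m.gene_ids, keep) if k]


def zhao_select(m: NormalizedMatrix, k_per_class: int = 40) -> list[str]:
    """Per class, top-k genes by |in-class median - out-of-class median|.

    Returns the deduplicated union over classes.  The published variant used
    k=40; a "widened" variant is simply a larger k.
    """
    labels = m.label_vector()
    classes = m.class_labels
    if len(classes) < 2:
        raise DataError("need at least 2 classes")
    selected: dict[str, None] = {}
    for c in classes:
        mask = labels == c
        if mask.sum() == 0 or (~mask).sum() == 0:
            raise DataError(f"class {c!r} has no samples in or out of class")
        diff = np.abs(np.median(m.values[:, mask], axis=1)
                      - np.median(m.values[:, ~mask], axis=1))
        order = sorted(range(m.n_genes),
                       key=lambda i: (-diff[i], m.gene_ids[i]))
        for i in order[:k_per_class]:
            selected.setdefault(m.gene_ids[i], None)
    return list(selected)


def optimize_subset(data: NormalizedMatrix, table: OcclusionScoreTable,
                    fractions: list[float],
                    cfg: NetworkConfig | None = None,
                    k: int = 5, repeats: int = 1, seed: int = 0
                    ) -> tuple[SubsetResult, list[SubsetResult]]:
    """Retrain on each top-fraction subset; return the most accurate.

    Ties in mean CV accuracy go to the smaller subset.
    """
    if not fractions:
        raise ValueError("fractions must be non-empty")
    ranking = rank_by_mean_occlusion(table)
    results = []
    for fraction in fractions:
        genes = select_top_fraction(ranking, fraction)
        sub = data.subset_genes(genes)
        cv = cross_validate(sub, cfg, k=k, repeats=repeats, seed=seed)
        results.append(SubsetResult(
            "occlusion-mean", fraction, genes, cv["fold_accuracies"],
            cv["mean_accuracy"], cv["median_accuracy"],
        ))
    best = max(results,
               key=lambda r: (r.mean_accuracy, -len(r.gene_ids)))
    return best, results


def depletion_study(data: NormalizedMatrix, subset_genes: list[str],
                    excluded: set[str],
                    cfg: NetworkConfig | None = None,
                    k: int = 5, repeats: int = 1, seed: int = 0) -> float:
    """Accuracy(subset) - accuracy(subset minus excluded genes).

    A positive delta means the excluded genes were contributing; near zero
    means they were dispensable.
    """
    unknown = set(excluded) - set(subset_genes)
    if unknown:
        raise DataError(f"excluded genes not in subset: {sorted(unknown)[:5]}")
    full = cross_validate(data.subset_genes(list(subset_genes)), cfg,
                          k=k, repeats=repeats, seed=seed)
    remaining = [g for g in subset_genes if g not in excluded]
    if not excluded:
        return 0.0
    if not remaining:
        raise DataError("excluding all genes leaves nothing to train on")
    depleted = cross_validate(data.subset_genes(remaining), cfg,
                              k=k, repeats=repeats, seed=seed)
    return float(full["mean_accuracy"] - depleted["mean_accuracy"])
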