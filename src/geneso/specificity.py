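"""Shannon-entropy tissue specificity and its relation to occlusion scores.

A gene's per-class profile (median expression per class) is normalized to
proportions p; the specificity score is

    Q = log2(N) - H,    H = -sum_c p_c log2 p_c   (0 log 0 := 0)

so Q ranges from 0 (uniform expression over the N classes) to log2(N)
(expression confined to a single class — complete tissue specificity; for
N = 28 the maximum is log2(28) = 4.8074 bits).  A [0, 1]-normalized variant
(Q / log2 N) is available behind a flag.  Correlation with per-gene mean
occlusion scores uses Pearson or Spearman coefficients.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from ._containers import DataError, NormalizedMatrix, OcclusionScoreTable

__all__ = [
    "build_class_profile",
    "shannon_specificity",
    "specificity_scores",
    "correlate",
    "specificity_table",
]


def build_class_profile(m: NormalizedMatrix,
                        labels: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-gene, per-class median expression (genes x classes DataFrame)."""
    labels = labels if labels is not None else m.labels
    lab = np.array([labels[s] for s in m.sample_ids], dtype=object)
    classes = sorted(set(lab))
    if not classes:
        raise DataError("no classes")
    cols = {}
    for c in classes:
        mask = lab == c
        if mask.sum() == 0:
            raise DataError(f"class {c!r} has no samples")
        cols[c] = np.median(m.values[:, mask], axis=1)
    return pd.DataFrame(cols, index=m.gene_ids)


def shannon_specificity(profile_row: np.ndarray, n_classes: int | None = None,
                        normalized: bool = False) -> float:
    """log2(N) minus the Shannon entropy of the proportion profile."""
    row = np.asarray(profile_row, dtype=float)
    if np.any(row < 0):
        raise DataError("expression profile must be non-negative")
    total = row.sum()
    if total <= 0:
        raise DataError("all-zero profile has undefined specificity")
    n = n_classes if n_classes is not None else row.size
    if n < row.size:
        raise ValueError("n_classes smaller than the profile length")
    p = row / total
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    score = np.log2(n) - entropy
    return score / np.log2(n) if normalized else float(score)


def specificity_scores(profile: pd.DataFrame,
                       normalized: bool = False) -> pd.Series:
    """Row-wise specificity of a genes x classes profile."""
    n = profile.shape[1]
    return pd.Series(
        [shannon_specificity(profile.iloc[i].to_numpy(), n,
                             normalized=normalized)
         for i in range(profile.shape[0])],
        index=profile.index, name="shannon_specificity",
    )


def correlate(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> float:
    """Pearson or Spearman correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d arrays of length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("correlation undefined for zero-variance input")
    if method == "pearson":
        return float(scipy.stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(scipy.stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def specificity_table(m: NormalizedMatrix, table: OcclusionScoreTable,
                      normalized: bool = False) -> pd.DataFrame:
    """Joint (gene, shannon_specificity, mean_occlusion_score) table.

    The scatter-plot input for asking whether the occlusion method merely
    rediscovers tissue specificity.  Genes with all-zero profiles are
    dropped (their specificity is undefined).
    """
    profile = build_class_profile(m)
    keep = profile.sum(axis=1) > 0
    spec = specificity_scores(profile.loc[keep], normalized=normalized)
    mean_occ = pd.Series(table.mean_scores, index=table.gene_ids,
                         name="mean_occlusion_score")
    out = pd.concat([spec, mean_occ], axis=1, join="inner")
    out.index.name = "gene_id"
    return out
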