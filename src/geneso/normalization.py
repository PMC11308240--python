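"""Read-count normalizations (NRC, TPM, RPKM) and the z-score transform.

NRC ("normalized counts") divides each gene's reads by the sample's total
mapped reads, so every column sums to one.  It deliberately drops both the
scaling constant and the gene-length term of TPM/RPKM: the classifier's
in-network z-score layer makes constants redundant, and gene length affects
every sample of a gene identically, so it carries no between-sample signal.

    NRC  =        reads_mapped / total_mapped_reads
    TPM  = 1e6 * (reads/length) / sum_genes(reads/length)
    RPKM = 1e9 *  reads / (total_reads * length)

"Total mapped reads" is the column sum of the supplied matrix; upstream
multimapper policy is out of scope.
"""

from __future__ import annotations

import numpy as np

from ._containers import (
    AlignmentError,
    CountMatrix,
    DegenerateSampleError,
    GenesoError,
    NormalizedMatrix,
    ZScoreStats,
)

__all__ = [
    "compute_nrc",
    "compute_tpm",
    "compute_rpkm",
    "normalize",
    "zscore_fit",
    "zscore_apply",
]


class ConfigurationError(GenesoError):
    pass


def _column_totals(cm: CountMatrix) -> np.ndarray:
    totals = cm.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        bad = [cm.sample_ids[i] for i in zero[:5]]
        raise DegenerateSampleError(f"samples with zero total reads: {bad}")
    return totals


def _lengths_vector(cm: CountMatrix, lengths: dict[str, int]) -> np.ndarray:
    missing = [g for g in cm.gene_ids if g not in lengths]
    if missing:
        raise ConfigurationError(f"genes without a length: {missing[:5]}")
    vec = np.array([lengths[g] for g in cm.gene_ids], dtype=float)
    if np.any(vec <= 0):
        raise ConfigurationError("gene lengths must be positive")
    return vec


def compute_nrc(cm: CountMatrix) -> NormalizedMatrix:
    """Reads mapped to a gene over total mapped reads of the sample."""
    totals = _column_totals(cm)
    return NormalizedMatrix(list(cm.gene_ids), list(cm.sample_ids),
                            cm.counts / totals, "NRC", dict(cm.labels))


def compute_tpm(cm: CountMatrix, lengths: dict[str, int]) -> NormalizedMatrix:
    """Transcripts per million; columns sum to 1e6."""
    rate = cm.counts / _lengths_vector(cm, lengths)[:, None]
    denom = rate.sum(axis=0)
    zero = np.flatnonzero(denom == 0)
    if zero.size:
        bad = [cm.sample_ids[i] for i in zero[:5]]
        raise DegenerateSampleError(f"samples with zero total reads: {bad}")
    return NormalizedMatrix(list(cm.gene_ids), list(cm.sample_ids),
                            1e6 * rate / denom, "TPM", dict(cm.labels))


def compute_rpkm(cm: CountMatrix, lengths: dict[str, int]) -> NormalizedMatrix:
    """Reads per kilobase of transcript per million mapped reads."""
    totals = _column_totals(cm)
    vec = _lengths_vector(cm, lengths)
    values = 1e9 * cm.counts / (totals[None, :] * vec[:, None])
    return NormalizedMatrix(list(cm.gene_ids), list(cm.sample_ids),
                            values, "RPKM", dict(cm.labels))


def normalize(cm: CountMatrix, method: str,
              lengths: dict[str, int] | None = None) -> NormalizedMatrix:
    """Dispatch on method name (case-insensitive: nrc, tpm, rpkm)."""
    method = method.lower()
    if method == "nrc":
        return compute_nrc(cm)
    if method in ("tpm", "rpkm"):
        if lengths is None:
            raise ConfigurationError(f"{method.upper()} requires gene lengths")
        return (compute_tpm if method == "tpm" else compute_rpkm)(cm, lengths)
    raise ValueError(f"unknown normalization method {method!r}")


def zscore_fit(training: NormalizedMatrix, ddof: int = 0) -> ZScoreStats:
    """Fit per-gene mean/std on the training split.

    Population std (``ddof=0``) by default; statistics are frozen and reused
    for validation and occlusion inputs.
    """
    mean = training.values.mean(axis=1)
    std = training.values.std(axis=1, ddof=ddof) if training.n_samples > ddof \
        else np.zeros(training.n_genes)
    return ZScoreStats(list(training.gene_ids), mean, std, ddof=ddof)


def zscore_apply(stats: ZScoreStats, values: np.ndarray,
                 gene_ids: list[str] | None = None) -> np.ndarray:
    """Apply frozen stats to a genes-x-samples array (or single row order).

    Genes with zero training variance map to 0 rather than NaN.
    """
    if gene_ids is not None and list(gene_ids) != list(stats.gene_ids):
        raise AlignmentError("gene order does not match fitted z-score stats")
    values = np.asarray(values, dtype=float)
    std = np.where(stats.std == 0, 1.0, stats.std)
    if values.ndim == 1:
        out = (values - stats.mean) / std
        return np.where(stats.std == 0, 0.0, out)
    out = (values - stats.mean[:, None]) / std[:, None]
    out[stats.std == 0, :] = 0.0
    return out
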