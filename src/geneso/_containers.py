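"""In-memory containers shared by all geneso modules.

The two matrix containers follow the count-tool convention: genes are rows,
samples are columns.  Class label order is canonical everywhere: the order in
which labels are first established (sorted unique labels unless an explicit
order is given) is frozen into models, score tables and prediction vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "OcclusionScoreTable",
    "ZScoreStats",
    "canonical_class_order",
]


class GenesoError(Exception):
    """Base class for all geneso domain errors."""


class FormatError(GenesoError):
    """Malformed on-disk artifact (duplicate ids, negative counts, ...)."""


class LabelledInputError(GenesoError):
    """Sample/label bookkeeping violated (missing or duplicate labels)."""


class AlignmentError(GenesoError):
    """Gene order of an input does not match the consumer's frozen order."""


class DataError(GenesoError):
    """Semantically invalid data for an operation (empty class, ...)."""


class DegenerateSampleError(DataError):
    """A sample is unusable (e.g. all-zero column under NRC)."""


class CorruptModelError(GenesoError):
    """Persisted model directory is incomplete or inconsistent."""


def canonical_class_order(labels: dict[str, str]) -> list[str]:
    """Sorted unique class labels — the canonical order used everywhere."""
    return sorted(set(labels.values()))


def _check_ids(ids: list[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate {what} id(s): {dupes[:5]}")


@dataclass
class CountMatrix:
    """Raw read counts, genes x samples, with per-sample class labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    labels: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_ids(self.gene_ids, "gene")
        _check_ids(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.counts)):
            raise FormatError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise FormatError("counts contain negative values")
        missing = [s for s in self.sample_ids if s not in self.labels]
        if missing:
            raise LabelledInputError(f"samples without labels: {missing[:5]}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def class_labels(self) -> list[str]:
        return canonical_class_order(
            {s: self.labels[s] for s in self.sample_ids}
        )

    def label_vector(self) -> np.ndarray:
        """Labels aligned to sample order, as an object array of strings."""
        return np.array([self.labels[s] for s in self.sample_ids], dtype=object)

    def subset_genes(self, genes: list[str]) -> "CountMatrix":
        idx = self._gene_index(genes)
        return CountMatrix(list(genes), list(self.sample_ids),
                           self.counts[idx, :], dict(self.labels))

    def _gene_index(self, genes: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise AlignmentError(f"genes absent from matrix: {missing[:5]}")
        return np.array([pos[g] for g in genes], dtype=int)


@dataclass
class NormalizedMatrix:
    """Normalized expression values tagged with the normalization method."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    method: str
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError("values shape does not match ids")
        if np.any(self.values < 0):
            raise FormatError("normalized values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def class_labels(self) -> list[str]:
        return canonical_class_order(
            {s: self.labels[s] for s in self.sample_ids}
        )

    def label_vector(self) -> np.ndarray:
        return np.array([self.labels[s] for s in self.sample_ids], dtype=object)

    def subset_genes(self, genes: list[str]) -> "NormalizedMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise AlignmentError(f"genes absent from matrix: {missing[:5]}")
        idx = np.array([pos[g] for g in genes], dtype=int)
        return NormalizedMatrix(list(genes), list(self.sample_ids),
                                self.values[idx, :], self.method,
                                dict(self.labels))


@dataclass
class ZScoreStats:
    """Per-gene mean/std fitted on a training split, with frozen gene order.

    ``ddof=0`` (population std) by default; genes with zero variance are
    mapped to 0 rather than NaN when applied.
    """

    gene_ids: list[str]
    mean: np.ndarray
    std: np.ndarray
    ddof: int = 0

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        n = len(self.gene_ids)
        if self.mean.shape != (n,) or self.std.shape != (n,):
            raise FormatError("z-score stats length must equal gene count")
        if np.any(self.std < 0):
            raise FormatError("std must be non-negative")


@dataclass
class OcclusionScoreTable:
    """Per-(gene, class) occlusion scores plus the per-gene mean.

    ``scores`` is genes x classes; the mean occlusion score is always the
    row mean over classes and is recomputed, never stored independently.
    """

    gene_ids: list[str]
    class_labels: list[str]
    scores: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.gene_ids), len(self.class_labels)):
            raise FormatError("score table shape mismatch")
        if self.scores.size and (
            np.any(self.scores < -1e-12) or np.any(self.scores > 1 + 1e-12)
        ):
            raise FormatError("occlusion scores must lie in [0, 1]")

    @property
    def mean_scores(self) -> np.ndarray:
        return self.scores.mean(axis=1)

    def mean_score_of(self, gene_id: str) -> float:
        try:
            i = self.gene_ids.index(gene_id)
        except ValueError as exc:
            raise DataError(f"gene {gene_id!r} not in score table") from exc
        return float(self.scores[i].mean())
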