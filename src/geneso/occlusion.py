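"""Symmetrical Occlusion: perturbation-based gene attribution.

For one gene in one reference sample, a grid of "occlusion values" replaces
the gene's normalized expression: the gain-of-function branch climbs from the
original value in steps of one tenth of that value until the grid would
exceed twice the sample's maximum expression, and the loss-of-function branch
descends symmetrically down to and including zero.  Each grid point yields a
pseudo sample differing from the reference in exactly that one gene; the
pseudo samples are pushed through the trained classifier and the fluctuation
of the prediction scores quantifies the gene's importance.

The occlusion score of (gene, class) is the |max - min| of the class's
prediction score along a reference sample's combined gain+loss trace,
averaged over same-class reference samples; the mean occlusion score averages
over all classes and is the global importance used for ranking.

Occlusion operates on the model's input scale (the normalized values before
the in-network z-score).  Grid points outside a gene's observed expression
range are biologically impossible; they are flagged "imaginary" for
reporting but participate in scoring exactly like real ones — they are an
intended part of the simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._containers import (
    AlignmentError,
    DataError,
    DegenerateSampleError,
    NormalizedMatrix,
    OcclusionScoreTable,
)
from .classifier import LSTMClassifier, _check_alignment

__all__ = [
    "OcclusionConfig",
    "PseudoSampleSet",
    "OcclusionTrace",
    "generate_pseudo_samples",
    "trace_gene",
    "occlusion_score",
    "mean_occlusion_score",
    "score_all_genes",
    "expression_sweep",
    "trace_to_frame",
]


@dataclass
class OcclusionConfig:
    """Grid and reference-sample policy for symmetrical occlusion.

    ``step_fraction`` — step as a fraction of the original expression
    (default 1/10).  ``max_multiplier`` — gain grid stops at this multiple of
    the sample's maximum expression (default 2).  For a zero-expression gene
    the step falls back to ``step_fraction * sample_max`` (the documented
    sample_max/10 at the default fraction).  ``absolute_step`` overrides the
    relative rule.  ``max_steps`` bounds each branch's grid length: when the
    rule would exceed it, the step is enlarged so the same range is covered
    in ``max_steps`` even steps (a runtime guard for near-zero expression
    values; generous enough to be inactive on typical grids).
    ``reference_cap`` limits reference samples per class, subsampled with
    ``seed``.  ``reference_scope`` selects whose references feed a class's
    score: ``own_class`` (default) averages class c's score fluctuation over
    class-c references only; ``all`` tracks class c's score curve on every
    reference regardless of its label — the cross-class variant, which
    rewards genes whose perturbation pulls foreign samples toward (or pushes
    native samples away from) a class.
    """

    step_fraction: float = 0.1
    max_multiplier: float = 2.0
    absolute_step: float | None = None
    max_steps: int = 1000
    direction: str = "both"          # gain | loss | both
    reference_cap: int | None = None
    reference_scope: str = "own_class"   # own_class | all
    seed: int = 0

    def __post_init__(self) -> None:
        if self.step_fraction <= 0:
            raise ValueError("step_fraction must be positive")
        if self.max_multiplier <= 0:
            raise ValueError("max_multiplier must be positive")
        if self.direction not in ("gain", "loss", "both"):
            raise ValueError("direction must be gain, loss or both")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if self.reference_scope not in ("own_class", "all"):
            raise ValueError("reference_scope must be own_class or all")


@dataclass
class PseudoSampleSet:
    """Occlusion grid for one (reference sample, gene).

    ``gain_values`` are strictly increasing and all above the original;
    ``loss_values`` are strictly decreasing, end at exactly 0.  The ``*_real``
    flags mark grid points inside the biologically observed range; points
    outside are "imaginary" (recorded for reporting only).
    """

    gene_id: str
    original: float
    gain_values: np.ndarray
    loss_values: np.ndarray
    gain_real: np.ndarray
    loss_real: np.ndarray
    reference_id: str | None = None
    class_label: str | None = None

    def values_ascending(self, include_original: bool = True) -> np.ndarray:
        parts = [self.loss_values[::-1]]
        if include_original:
            parts.append(np.array([self.original]))
        parts.append(self.gain_values)
        return np.concatenate(parts)


def _branch_grids(original: float, sample_max: float,
                  cfg: OcclusionConfig) -> tuple[np.ndarray, np.ndarray]:
    """(gain ascending, loss descending) occlusion values."""
    if cfg.absolute_step is not None:
        step = cfg.absolute_step
    elif original > 0:
        step = cfg.step_fraction * original
    else:
        step = cfg.step_fraction * sample_max

    bound = cfg.max_multiplier * sample_max
    # tolerant count so e.g. (40 - 10) / 0.1 lands on exactly 300 steps
    span = bound - original
    if span <= 0 or cfg.direction == "loss":
        gain = np.empty(0)
    else:
        n = int(np.floor(span / step * (1 + 1e-12) + 1e-9))
        if n > cfg.max_steps:
            n = cfg.max_steps
            gain = original + (span / n) * np.arange(1, n + 1)
        else:
            gain = original + step * np.arange(1, n + 1)

    if original <= 0 or cfg.direction == "gain":
        loss = np.empty(0)
    else:
        m = int(np.ceil(original / step * (1 - 1e-12))) - 1
        if m > cfg.max_steps - 1:
            m = cfg.max_steps - 1
            loss_step = original / (m + 1)
        else:
            loss_step = step
        loss = np.concatenate([original - loss_step * np.arange(1, m + 1),
                               [0.0]])
    return gain, loss


def generate_pseudo_samples(reference: np.ndarray, gene: str | int,
                            cfg: OcclusionConfig | None = None,
                            gene_ids: list[str] | None = None,
                            observed_range: tuple[float, float] | None = None,
                            reference_id: str | None = None,
                            class_label: str | None = None) -> PseudoSampleSet:
    """Build the gain/loss occlusion grid for one gene of one sample.

    ``gene`` may be an integer position or a gene id (requires ``gene_ids``).
    ``observed_range`` is the gene's (min, max) across the training set, the
    boundary between real and imaginary values; when omitted, the reference
    sample's own range [0, max] is used.
    """
    cfg = cfg or OcclusionConfig()
    reference = np.asarray(reference, dtype=float)
    if isinstance(gene, str):
        if gene_ids is None:
            raise AlignmentError("gene id given but no gene_ids to resolve it")
        try:
            gi = list(gene_ids).index(gene)
        except ValueError as exc:
            raise AlignmentError(f"gene {gene!r} absent from vector") from exc
        gene_name = gene
    else:
        gi = int(gene)
        gene_name = gene_ids[gi] if gene_ids is not None else f"g{gi}"
    if np.any(reference < 0):
        raise DataError("expression values must be non-negative")
    sample_max = float(reference.max())
    if sample_max <= 0:
        raise DegenerateSampleError("all-zero reference sample")

    original = float(reference[gi])
    gain, loss = _branch_grids(original, sample_max, cfg)
    lo, hi = observed_range if observed_range is not None else (0.0, sample_max)
    return PseudoSampleSet(
        gene_id=gene_name, original=original,
        gain_values=gain, loss_values=loss,
        gain_real=(gain >= lo) & (gain <= hi),
        loss_real=(loss >= lo) & (loss <= hi),
        reference_id=reference_id, class_label=class_label,
    )


@dataclass
class OcclusionTrace:
    """Per-class prediction scores along one gene's occlusion grid."""

    gene_id: str
    reference_id: str | None
    original: float
    occlusion_values: np.ndarray          # ascending, includes the original
    scores: np.ndarray                    # (n_values, n_classes)
    class_labels: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.occlusion_values)

    def class_scores(self, class_label: str) -> np.ndarray:
        try:
            ci = self.class_labels.index(class_label)
        except ValueError as exc:
            raise DataError(f"class {class_label!r} not in trace") from exc
        return self.scores[:, ci]

    def score_range(self, class_label: str) -> float:
        """|max - min| of the class's prediction score along the trace."""
        s = self.class_scores(class_label)
        return float(s.max() - s.min())


def _forward_chunked(model: LSTMClassifier, X: np.ndarray,
                     chunk: int = 2048) -> np.ndarray:
    if X.shape[0] <= chunk:
        return model.predict_proba(X)
    return np.vstack([model.predict_proba(X[i:i + chunk])
                      for i in range(0, X.shape[0], chunk)])


def _pseudo_matrix(reference: np.ndarray, gi: int,
                   values: np.ndarray) -> np.ndarray:
    rows = np.tile(reference, (len(values), 1))
    rows[:, gi] = values
    return rows


def trace_gene(model: LSTMClassifier, reference: np.ndarray, gene: str | int,
               cfg: OcclusionConfig | None = None,
               reference_id: str | None = None,
               observed_range: tuple[float, float] | None = None
               ) -> OcclusionTrace:
    """Forward every pseudo sample plus the unmodified reference."""
    cfg = cfg or OcclusionConfig()
    gene_ids = model.gene_ids_
    if isinstance(gene, str) and gene_ids is None:
        raise AlignmentError("model has no gene order to resolve gene ids")
    pset = generate_pseudo_samples(reference, gene, cfg, gene_ids=gene_ids,
                                   observed_range=observed_range,
                                   reference_id=reference_id)
    gi = list(gene_ids).index(pset.gene_id) if gene_ids is not None \
        else int(gene)
    values = pset.values_ascending(include_original=True)
    scores = _forward_chunked(model, _pseudo_matrix(reference, gi, values))
    return OcclusionTrace(pset.gene_id, reference_id, pset.original,
                          values, scores, [str(c) for c in model.classes_])


def trace_to_frame(trace: OcclusionTrace) -> pd.DataFrame:
    """Long-format (gene, reference_sample, occlusion_value, class, score)."""
    n, c = trace.scores.shape
    return pd.DataFrame({
        "gene": np.repeat(trace.gene_id, n * c),
        "reference_sample": np.repeat(trace.reference_id, n * c),
        "occlusion_value": np.repeat(trace.occlusion_values, c),
        "class": np.tile(trace.class_labels, n),
        "score": trace.scores.ravel(),
    })


def _class_references(data: NormalizedMatrix, class_label: str,
                      cap: int | None, rng: np.random.Generator
                      ) -> list[int]:
    idx = [i for i, s in enumerate(data.sample_ids)
           if data.labels.get(s) == class_label]
    if not idx:
        raise DataError(f"no reference samples for class {class_label!r}")
    if cap is not None and len(idx) > cap:
        sel = rng.choice(len(idx), size=cap, replace=False)
        idx = [idx[k] for k in sorted(sel)]
    return idx


def occlusion_score(model: LSTMClassifier, data: NormalizedMatrix,
                    gene: str, class_label: str,
                    cfg: OcclusionConfig | None = None,
                    reference_ids: list[str] | None = None) -> float:
    """Mean per-reference |max - min| of the class's score for one gene."""
    cfg = cfg or OcclusionConfig()
    _check_alignment(model, data)
    if reference_ids is None:
        rng = np.random.default_rng(cfg.seed)
        ref_idx = _class_references(data, class_label, cfg.reference_cap, rng)
    else:
        pos = {s: i for i, s in enumerate(data.sample_ids)}
        missing = [s for s in reference_ids if s not in pos]
        if missing:
            raise DataError(f"unknown reference samples: {missing[:5]}")
        wrong = [s for s in reference_ids
                 if data.labels.get(s) != class_label]
        if wrong:
            raise DataError(
                f"reference samples not labelled {class_label!r}: {wrong[:5]}")
        ref_idx = [pos[s] for s in reference_ids]
    if not ref_idx:
        raise DataError("empty reference set")
    diffs = []
    for i in ref_idx:
        trace = trace_gene(model, data.values[:, i], gene, cfg,
                           reference_id=data.sample_ids[i])
        diffs.append(trace.score_range(class_label))
    return float(np.mean(diffs))


def mean_occlusion_score(per_class_scores: dict[str, float],
                         class_labels: list[str]) -> float:
    """Arithmetic mean of a gene's occlusion scores over all classes."""
    missing = [c for c in class_labels if c not in per_class_scores]
    if missing:
        raise DataError(f"missing occlusion score for classes: {missing[:5]}")
    return float(np.mean([per_class_scores[c] for c in class_labels]))


def score_all_genes(model: LSTMClassifier, data: NormalizedMatrix,
                    cfg: OcclusionConfig | None = None,
                    genes: list[str] | None = None) -> OcclusionScoreTable:
    """Occlusion score for every (gene, class): the ranking summary table.

    Reference samples are, per class, all samples of that class in ``data``
    (typically the validation split), optionally capped with seeded
    subsampling.  Per gene, all reference grids are batched into as few
    forward passes as possible.
    """
    cfg = cfg or OcclusionConfig()
    _check_alignment(model, data)
    classes = [str(c) for c in model.classes_]
    data_classes = set(data.labels[s] for s in data.sample_ids)
    missing = [c for c in classes if c not in data_classes]
    if missing:
        raise DataError(f"classes without reference samples: {missing[:5]}")

    rng = np.random.default_rng(cfg.seed)
    refs: list[tuple[int, int]] = []          # (sample position, class index)
    for ci, c in enumerate(classes):
        for i in _class_references(data, c, cfg.reference_cap, rng):
            refs.append((i, ci))

    gene_list = list(genes) if genes is not None else list(data.gene_ids)
    gpos = {g: i for i, g in enumerate(data.gene_ids)}
    absent = [g for g in gene_list if g not in gpos]
    if absent:
        raise AlignmentError(f"genes absent from data: {absent[:5]}")

    cross = cfg.reference_scope == "all"
    scores = np.zeros((len(gene_list), len(classes)))
    counts = np.full(len(classes), float(len(refs))) if cross \
        else np.zeros(len(classes))
    if not cross:
        for _, ci in refs:
            counts[ci] += 1
    for gr, g in enumerate(gene_list):
        gi = gpos[g]
        blocks, spans = [], []
        for si, ci in refs:
            ref_vec = data.values[:, si]
            pset = generate_pseudo_samples(ref_vec, gi, cfg)
            vals = pset.values_ascending(include_original=True)
            blocks.append(_pseudo_matrix(ref_vec, gi, vals))
            spans.append((ci, len(vals)))
        probs = _forward_chunked(model, np.vstack(blocks))
        start = 0
        for ci, n in spans:
            block = probs[start:start + n]
            if cross:
                scores[gr] += block.max(axis=0) - block.min(axis=0)
            else:
                col = block[:, ci]
                scores[gr, ci] += float(col.max() - col.min())
            start += n
    scores /= counts[None, :]
    return OcclusionScoreTable(
        gene_list, classes, scores,
        provenance={
            "config": vars(cfg).copy(),
            "n_reference_samples": {c: int(counts[ci])
                                    for ci, c in enumerate(classes)},
        },
    )


def expression_sweep(model: LSTMClassifier, data: NormalizedMatrix,
                     gene: str, direction: str,
                     cfg: OcclusionConfig | None = None,
                     sample_ids: list[str] | None = None,
                     target_class: str | None = None) -> dict:
    """Gain- or loss-of-function sweep across many samples at once.

    For every occlusion step the predicted label of every sample is recorded
    (the heat-map view of a marker-gene perturbation).  Step 0 is the
    unmodified sample; grids are sample-specific, so samples whose grid ends
    early hold their final prediction for the remaining steps.  When
    ``target_class`` is given, the fraction of samples predicted as that
    class at each step is returned as well.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be gain or loss")
    cfg = cfg or OcclusionConfig()
    cfg = OcclusionConfig(**{**vars(cfg), "direction": direction})
    _check_alignment(model, data)
    if gene not in data.gene_ids:
        raise AlignmentError(f"gene {gene!r} absent from data")
    gi = data.gene_ids.index(gene)
    if sample_ids is None:
        sample_ids = list(data.sample_ids)
    pos = {s: i for i, s in enumerate(data.sample_ids)}
    grids = []
    for s in sample_ids:
        vec = data.values[:, pos[s]]
        pset = generate_pseudo_samples(vec, gi, cfg)
        branch = pset.gain_values if direction == "gain" else pset.loss_values
        grids.append((vec, np.concatenate([[pset.original], branch])))
    n_steps = max(len(g) for _, g in grids)
    labels = np.empty((len(sample_ids), n_steps), dtype=object)
    for r, (vec, vals) in enumerate(grids):
        preds = model.predict(_pseudo_matrix(vec, gi, vals))
        labels[r, :len(vals)] = preds
        labels[r, len(vals):] = preds[-1]
    out = {"sample_ids": list(sample_ids), "labels": labels,
           "n_steps": n_steps, "direction": direction, "gene": gene}
    if target_class is not None:
        out["target_fraction"] = (labels == target_class).mean(axis=0)
    return out
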