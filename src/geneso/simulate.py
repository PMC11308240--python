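"""Seeded negative-binomial count simulator with planted marker genes.

Emulates the statistical structure the classifier and occlusion method
assume: C classes (tissue/status or cell type), n samples per class, G genes
with log-normal baseline means, per-sample log-normal library-size factors,
and m marker genes per class whose mean is multiplied by a fold-change in
their own class (one-vs-rest, mirroring classic single-class markers).
Counts are negative-binomial with a common dispersion; a zero-inflation
option produces scRNA-like sparsity.  The ground-truth class -> marker map
is returned so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._containers import CountMatrix

__all__ = ["SyntheticConfig", "simulate_counts", "simulate_sc_counts",
           "simulate_gene_lengths"]


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give a compact 4-class bulk design."""

    n_classes: int = 4
    samples_per_class: int = 30
    n_genes: int = 600
    markers_per_class: int = 5
    baseline_mean: float = 50.0          # mean reads per gene before scaling
    dispersion: float = 2.0              # NB size parameter r; var = mu + mu^2/r
    fold_change: float = 8.0             # marker multiplier in its own class
    library_sigma: float = 0.2           # log-normal sd of library factors
    gene_mean_sigma: float = 1.0         # log-normal sd of baseline means
    sparsity: float = 0.0                # zero-inflation probability
    marker_placement: str = "random"     # markers interspersed ("random") or
                                         # contiguous leading genes ("block")
    exclusive_marker: bool = False       # class 0's first marker off elsewhere
    class_prefix: str = "class"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError("more markers than genes")
        if self.fold_change < 1:
            raise ValueError("fold change must be >= 1")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.marker_placement not in ("random", "block"):
            raise ValueError("marker_placement must be 'random' or 'block'")
        if min(self.baseline_mean, self.dispersion,
               self.samples_per_class) <= 0:
            raise ValueError("rates and sizes must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             r: float) -> np.ndarray:
    # numpy parametrizes NB by (n, p) with mean n(1-p)/p; p = r/(r+mu)
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(cfg: SyntheticConfig | None = None
                    ) -> tuple[CountMatrix, dict[str, list[str]]]:
    """Generate a labelled count matrix plus the marker truth table.

    Markers of class k are genes ``g{k*m}..g{k*m+m-1}``; the truth table maps
    each class label to its marker gene ids.  Deterministic given the seed.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    C, n, G, m = (cfg.n_classes, cfg.samples_per_class, cfg.n_genes,
                  cfg.markers_per_class)
    gene_ids = [f"g{i:04d}" for i in range(G)]
    sample_ids = [f"{cfg.class_prefix}{c}_s{j:03d}"
                  for c in range(C) for j in range(n)]
    labels = {f"{cfg.class_prefix}{c}_s{j:03d}": f"{cfg.class_prefix}{c}"
              for c in range(C) for j in range(n)}
    class_of = np.repeat(np.arange(C), n)

    base_mean = cfg.baseline_mean * rng.lognormal(
        -cfg.gene_mean_sigma ** 2 / 2, cfg.gene_mean_sigma, size=G)
    lib = rng.lognormal(-cfg.library_sigma ** 2 / 2, cfg.library_sigma,
                        size=C * n)

    truth: dict[str, list[str]] = {}
    marker_of = np.full(G, -1)
    if cfg.marker_placement == "random":
        marker_pool = rng.choice(G, size=C * m, replace=False)
    else:
        marker_pool = np.arange(C * m)
    for c in range(C):
        idx = np.sort(marker_pool[c * m:(c + 1) * m])
        marker_of[idx] = c
        truth[f"{cfg.class_prefix}{c}"] = [gene_ids[i] for i in idx]

    mu = base_mean[:, None] * lib[None, :]
    is_marker = marker_of >= 0
    boost = np.where(marker_of[:, None] == class_of[None, :],
                     cfg.fold_change, 1.0)
    mu = mu * np.where(is_marker[:, None], boost, 1.0)
    if cfg.exclusive_marker:
        # class 0's first marker: silent outside its own class
        first = int(np.flatnonzero(marker_of == 0)[0])
        mu[first, class_of != 0] = 0.0

    counts = np.zeros_like(mu)
    pos = mu > 0
    counts[pos] = _nb_draw(rng, mu[pos], cfg.dispersion)
    if cfg.sparsity > 0:
        counts *= rng.random(counts.shape) >= cfg.sparsity
    return CountMatrix(gene_ids, sample_ids, counts, labels), truth


def simulate_sc_counts(cfg: SyntheticConfig | None = None
                       ) -> tuple[CountMatrix, dict[str, list[str]]]:
    """scRNA-like variant: sparse counts, cell-type labels, and one cell
    type with an exclusive marker (zero expression in every other type)."""
    cfg = cfg or SyntheticConfig()
    overrides = dict(vars(cfg))
    overrides.update(
        sparsity=cfg.sparsity if cfg.sparsity > 0 else 0.6,
        baseline_mean=min(cfg.baseline_mean, 5.0),
        exclusive_marker=True,
        class_prefix="celltype",
    )
    return simulate_counts(SyntheticConfig(**overrides))


def simulate_gene_lengths(gene_ids: list[str], seed: int = 0,
                          low: int = 300, high: int = 20000
                          ) -> dict[str, int]:
    """Companion gene-length table for TPM/RPKM exercises."""
    rng = np.random.default_rng(seed)
    return {g: int(rng.integers(low, high)) for g in gene_ids}
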