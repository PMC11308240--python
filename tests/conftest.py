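"""Shared fixtures: small synthetic datasets and one full study pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

import geneso as gs

STUDY_SEED = 1


@pytest.fixture
def tiny_counts() -> gs.CountMatrix:
    """3 genes x 2 samples with fixed values for hand-checked arithmetic."""
    return gs.CountMatrix(
        ["gA", "gB", "gC"], ["s1", "s2"],
        np.array([[5.0, 2.0], [15.0, 6.0], [0.0, 12.0]]),
        {"s1": "tumour", "s2": "normal"},
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Compact, cleanly separable dataset: 3 classes x 8 samples, 30 genes,
    3 markers per class, low biological noise (dispersion 20)."""
    cfg = gs.SyntheticConfig(n_classes=3, samples_per_class=8, n_genes=30,
                             markers_per_class=3, dispersion=20.0, seed=5)
    cm, truth = gs.simulate_counts(cfg)
    return gs.compute_nrc(cm), truth


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """Quickly trained classifier on the compact dataset."""
    nm, _ = small_dataset
    cfg = gs.NetworkConfig(hidden_sizes=(8, 6), timesteps=1, epochs=120,
                           seed=0)
    return gs.train(nm, cfg, seed=0)


def run_study(seed: int) -> dict:
    """The scaled-down end-to-end study: simulate, train, occlude, rank.

    Conditions: 4 classes x 30 samples, 600 genes, 5 planted markers per
    class at fold-change 8; NRC input; reduced network (hidden [32, 16],
    single-timestep layout); occlusion over all genes with 3 validation
    reference samples per class and grids capped at 100 steps per branch.
    """
    cm, truth = gs.simulate_counts(gs.SyntheticConfig(seed=seed))
    nm = gs.compute_nrc(cm)
    y = nm.label_vector()
    X = nm.values.T
    train_idx, val_idx = train_test_split(
        np.arange(len(y)), test_size=0.25, stratify=y, random_state=seed)
    model = gs.LSTMClassifier(hidden_sizes=(32, 16), timesteps=1,
                              epochs=300, weight_decay=1e-3,
                              random_state=seed)
    model.fit(X[train_idx], y[train_idx], gene_ids=list(nm.gene_ids))
    val_ids = [nm.sample_ids[i] for i in val_idx]
    validation = gs.NormalizedMatrix(
        list(nm.gene_ids), val_ids, nm.values[:, val_idx], "NRC",
        {s: nm.labels[s] for s in val_ids})
    occ = gs.OcclusionConfig(reference_cap=3, max_steps=100, seed=seed)
    table = gs.score_all_genes(model, validation, occ)
    ranking = gs.rank_by_mean_occlusion(table)
    return {
        "seed": seed,
        "truth": truth,
        "markers": {g for genes in truth.values() for g in genes},
        "data": nm,
        "validation": validation,
        "model": model,
        "occlusion_config": occ,
        "table": table,
        "ranking": ranking,
        "validation_accuracy": model.score(X[val_idx], y[val_idx]),
    }


@pytest.fixture(scope="session")
def study():
    return run_study(STUDY_SEED)
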