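"""LSTM expression classifier with a scikit-learn estimator interface.

The network is the in-package numpy stack (:mod:`geneso.nn`): a z-score input
layer whose statistics are fit on the training split only, the length-G
expression vector reshaped into T timesteps x F features (T = ceil(sqrt(G))
by default, zero-padded), two LSTM layers (120 and 80 cells by default) each
followed by 30% dropout during training, and a fully connected softmax head.
Classification is the argmax of the softmax scores; ties break to the lowest
class index.

The z-score layer is bounded: |z| is clipped at ``zscore_clip`` (default 10)
so that inputs far outside the training distribution — occlusion grids reach
many standard deviations for low-variance genes — cannot drive the network
into arbitrary extrapolation.  Values inside the clip are untouched, so
ordinary classification is unaffected; set ``zscore_clip=None`` for the
unbounded layer.

``LSTMClassifier`` composes with sklearn model selection; ``train`` and
``cross_validate`` are thin wrappers over it operating on
:class:`~geneso._containers.NormalizedMatrix` inputs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split

from ._containers import (
    AlignmentError,
    DataError,
    NormalizedMatrix,
    ZScoreStats,
)
from .nn import AdamOptimizer, LSTMNetwork
from .normalization import zscore_apply

__all__ = ["LSTMClassifier", "NetworkConfig", "train", "cross_validate",
           "flag_novel", "predict_matrix"]


@dataclass
class NetworkConfig:
    """Architecture + optimizer settings, serializable to YAML."""

    hidden_sizes: tuple[int, ...] = (120, 80)
    dropout: float = 0.3
    peephole: bool = True
    timesteps: int | None = None     # None -> ceil(sqrt(n_genes))
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    augment_fraction: float = 0.0
    zscore_clip: float | None = 10.0
    epochs: int = 60
    batch_size: int = 32
    early_stopping: bool = False
    validation_fraction: float = 0.1
    patience: int = 10
    zscore_ddof: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["hidden_sizes"] = list(self.hidden_sizes)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


class LSTMClassifier(ClassifierMixin, BaseEstimator):
    """Two-layer (peephole) LSTM softmax classifier over expression vectors.

    Parameters mirror :class:`NetworkConfig`.  Fitted attributes:

    - ``classes_`` — canonical class label order (sorted unique labels)
    - ``gene_ids_`` — frozen gene order (feature names), if provided
    - ``zscore_`` — per-gene training mean/std applied by the input layer
    - ``network_`` — the underlying :class:`~geneso.nn.LSTMNetwork`
    - ``timesteps_``, ``features_per_step_`` — sequence layout
    - ``loss_curve_`` — mean training cross-entropy per epoch
    """

    def __init__(self, hidden_sizes=(120, 80), dropout=0.3, peephole=True,
                 timesteps=None, learning_rate=1e-3, weight_decay=1e-3,
                 augment_fraction=0.0, zscore_clip=10.0,
                 epochs=60, batch_size=32,
                 early_stopping=False, validation_fraction=0.1, patience=10,
                 zscore_ddof=0, random_state=0):
        self.hidden_sizes = hidden_sizes
        self.dropout = dropout
        self.peephole = peephole
        self.timesteps = timesteps
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.augment_fraction = augment_fraction
        self.zscore_clip = zscore_clip
        self.epochs = epochs
        self.batch_size = batch_size
        self.early_stopping = early_stopping
        self.validation_fraction = validation_fraction
        self.patience = patience
        self.zscore_ddof = zscore_ddof
        self.random_state = random_state

    @classmethod
    def from_config(cls, cfg: NetworkConfig) -> "LSTMClassifier":
        return cls(hidden_sizes=cfg.hidden_sizes, dropout=cfg.dropout,
                   peephole=cfg.peephole, timesteps=cfg.timesteps,
                   learning_rate=cfg.learning_rate,
                   weight_decay=cfg.weight_decay,
                   augment_fraction=cfg.augment_fraction,
                   zscore_clip=cfg.zscore_clip, epochs=cfg.epochs,
                   batch_size=cfg.batch_size, early_stopping=cfg.early_stopping,
                   validation_fraction=cfg.validation_fraction,
                   patience=cfg.patience, zscore_ddof=cfg.zscore_ddof,
                   random_state=cfg.seed)

    # -- input plumbing ------------------------------------------------------

    def _sequence_layout(self, n_genes: int) -> tuple[int, int]:
        T = self.timesteps or max(1, math.ceil(math.sqrt(n_genes)))
        F = math.ceil(n_genes / T)
        return T, F

    def _to_sequences(self, X: np.ndarray) -> np.ndarray:
        """Z-score then reshape (n_samples, G) -> (n_samples, T, F)."""
        Z = zscore_apply(self.zscore_, np.asarray(X, dtype=float).T).T
        if self.zscore_clip is not None:
            Z = np.clip(Z, -self.zscore_clip, self.zscore_clip)
        B, G = Z.shape
        T, F = self.timesteps_, self.features_per_step_
        padded = np.zeros((B, T * F))
        padded[:, :G] = Z
        return padded.reshape(B, T, F)

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y, gene_ids: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_genes) aligned with y")
        classes, y_idx = np.unique(y, return_inverse=True)
        if classes.size < 2:
            raise DataError("training requires at least 2 classes")
        counts = np.bincount(y_idx)
        if counts.min() < 1:
            raise DataError("every class needs at least one sample")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        self.gene_ids_ = list(gene_ids) if gene_ids is not None else None

        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=self.zscore_ddof) if X.shape[0] > self.zscore_ddof \
            else np.zeros(X.shape[1])
        ids = self.gene_ids_ or [f"f{i}" for i in range(X.shape[1])]
        self.zscore_ = ZScoreStats(ids, mean, std, ddof=self.zscore_ddof)
        self.timesteps_, self.features_per_step_ = self._sequence_layout(X.shape[1])

        rng = np.random.default_rng(self.random_state)
        net = LSTMNetwork(self.features_per_step_, tuple(self.hidden_sizes),
                          classes.size, peephole=self.peephole,
                          dropout=self.dropout, rng=rng)
        optimizer = AdamOptimizer(lr=self.learning_rate,
                                  weight_decay=self.weight_decay)

        onehot = np.eye(classes.size)[y_idx]
        X_train = X
        val_seqs = val_onehot = None
        if self.early_stopping and counts.min() >= 2:
            tr, va = train_test_split(
                np.arange(len(y_idx)), test_size=self.validation_fraction,
                stratify=y_idx, random_state=self.random_state)
            val_seqs, val_onehot = self._to_sequences(X[va]), onehot[va]
            X_train, onehot = X[tr], onehot[tr]
        seqs = self._to_sequences(X_train)

        n = X_train.shape[0]
        batch = min(self.batch_size, n)
        n_aug = int(round(self.augment_fraction * X_train.shape[1]))
        self.loss_curve_ = []
        best_val, best_weights, stall = np.inf, None, 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                if n_aug > 0:
                    # single-gene occlusion augmentation: replace a few genes
                    # per sample with uniform draws over the occlusion range
                    Xb = X_train[idx].copy()
                    for r in range(Xb.shape[0]):
                        cols = rng.choice(Xb.shape[1], size=n_aug,
                                          replace=False)
                        Xb[r, cols] = rng.uniform(
                            0, 2 * Xb[r].max(), size=n_aug)
                    batch_seqs = self._to_sequences(Xb)
                else:
                    batch_seqs = seqs[idx]
                loss, grads = net.loss_and_grads(batch_seqs, onehot[idx],
                                                 rng=rng)
                optimizer.step(net, grads)
                epoch_loss += loss * len(idx)
            self.loss_curve_.append(epoch_loss / n)
            if val_seqs is not None:
                probs = net.forward(val_seqs)
                val_loss = -np.mean(
                    np.log(np.sum(probs * val_onehot, axis=1) + 1e-12))
                if val_loss < best_val - 1e-6:
                    best_val, stall = val_loss, 0
                    best_weights = {k: v.copy()
                                    for k, v in net.parameter_dict().items()}
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_weights is not None:
            for k, v in best_weights.items():
                net.set_parameter(k, v)
        self.network_ = net
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Softmax prediction scores, rows aligned to ``classes_``."""
        if not hasattr(self, "network_"):
            raise DataError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise AlignmentError(
                f"input has {X.shape[1]} genes, model expects "
                f"{self.n_features_in_}")
        return self.network_.forward(self._to_sequences(X))

    def predict(self, X) -> np.ndarray:
        probs = self.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


def flag_novel(scores: np.ndarray, threshold: float = 0.7) -> bool:
    """True when the best class score stays below ``threshold``.

    Samples from classes the model never saw tend to produce flat, low
    maximum prediction scores; this marks such samples as candidate novel
    classes.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise DataError("expected one per-class score vector")
    return bool(scores.max() < threshold)


def _check_alignment(model: LSTMClassifier, nm: NormalizedMatrix) -> None:
    if model.gene_ids_ is not None and list(nm.gene_ids) != model.gene_ids_:
        raise AlignmentError("matrix gene order differs from model gene order")


def predict_matrix(model: LSTMClassifier, nm: NormalizedMatrix) -> np.ndarray:
    """Prediction scores (samples x classes) for a normalized matrix."""
    _check_alignment(model, nm)
    return model.predict_proba(nm.values.T)


def train(data: NormalizedMatrix, cfg: NetworkConfig | None = None,
          seed: int | None = None) -> LSTMClassifier:
    """Fit a classifier on a labelled normalized matrix."""
    cfg = cfg or NetworkConfig()
    model = LSTMClassifier.from_config(cfg)
    if seed is not None:
        model.set_params(random_state=seed)
    y = data.label_vector()
    return model.fit(data.values.T, y, gene_ids=list(data.gene_ids))


def cross_validate(data: NormalizedMatrix, cfg: NetworkConfig | None = None,
                   k: int = 5, repeats: int = 3, seed: int = 0) -> dict:
    """Repeated stratified k-fold cross-validation.

    Returns per-fold validation accuracies plus mean/median.  Folds are
    disjoint within a repeat and cover all samples; a class smaller than k
    triggers sklearn's stratification warning and degraded folding rather
    than an error.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cfg = cfg or NetworkConfig()
    base = LSTMClassifier.from_config(cfg)
    y = data.label_vector()
    X = data.values.T
    _, y_idx = np.unique(y, return_inverse=True)
    min_count = int(np.bincount(y_idx).min())
    if min_count < 2:
        raise DataError("cross-validation needs >= 2 samples per class")
    k_eff = k
    if min_count < k:
        warnings.warn("smallest class has fewer samples than k; "
                      "folding degraded to k="
                      f"{min_count}", UserWarning)
        k_eff = min_count
    splitter = RepeatedStratifiedKFold(n_splits=k_eff, n_repeats=repeats,
                                       random_state=seed)
    accuracies, fold_indices = [], []
    for tr, va in splitter.split(X, y_idx):
        model = clone(base)
        model.set_params(random_state=seed)
        model.fit(X[tr], y[tr], gene_ids=list(data.gene_ids))
        accuracies.append(model.score(X[va], y[va]))
        fold_indices.append((tr, va))
    accuracies = np.array(accuracies)
    return {
        "fold_accuracies": accuracies,
        "mean_accuracy": float(accuracies.mean()),
        "median_accuracy": float(np.median(accuracies)),
        "fold_indices": fold_indices,
        "k": k_eff,
        "repeats": repeats,
    }
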