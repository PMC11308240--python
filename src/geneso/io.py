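"""Readers and writers for all on-disk artifacts.

Dense count matrices are TSV/CSV with genes as rows (first column gene id,
header row of sample ids).  MatrixMarket triplets use 1-based indices and are
accompanied by plain-text row (gene) and column (sample) id files.  Labels and
gene lengths are 2-column TSVs.  Models persist as a directory holding a
weights blob (``weights.npz``) plus a JSON metadata sidecar so gene order,
z-score statistics and class labels stay inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._containers import (
    CorruptModelError,
    CountMatrix,
    DataError,
    FormatError,
    LabelledInputError,
    OcclusionScoreTable,
)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_labels",
    "write_labels",
    "read_gene_lengths",
    "write_gene_lengths",
    "read_gene_list",
    "write_gene_list",
    "read_score_table",
    "write_score_table",
    "save_model",
    "load_model",
]

MEAN_SCORE_COLUMN = "mean_occlusion_score"


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column (sample_id, class) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"label file {path} must have 2 columns")
    if df[0].duplicated().any():
        raise LabelledInputError(f"duplicate sample ids in label file {path}")
    return dict(zip(df[0], df[1]))


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(list(labels.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def _read_dense(path: Path, sep: str) -> tuple[list[str], list[str], np.ndarray]:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        raise FormatError(f"missing values in count matrix {path}")
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    return genes, samples, df.to_numpy(dtype=float)


def _read_mtx_triplet(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    mat = scipy.io.mmread(path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    rows = path.with_suffix(".rows.txt")
    cols = path.with_suffix(".cols.txt")
    for p in (rows, cols):
        if not p.exists():
            raise FormatError(f"MTX id sidecar missing: {p}")
    genes = rows.read_text().split()
    samples = cols.read_text().split()
    return genes, samples, np.asarray(mat, dtype=float)


def read_count_matrix(
    path: str | Path,
    labels_path: str | Path,
    format: str = "tsv",
) -> CountMatrix:
    """Read a genes-x-samples count matrix plus its sample-label table.

    ``format`` is one of ``tsv``, ``csv`` or ``mtx_triplet``.  Sample order
    is preserved from the matrix file; every sample must appear in the label
    table.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        genes, samples, counts = _read_dense(path, "\t")
    elif format == "csv":
        genes, samples, counts = _read_dense(path, ",")
    elif format == "mtx_triplet":
        genes, samples, counts = _read_mtx_triplet(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    labels = read_labels(labels_path)
    return CountMatrix(genes, samples, counts,
                       {s: labels[s] for s in samples if s in labels})


def write_count_matrix(cm: CountMatrix, path: str | Path,
                       labels_path: str | Path | None = None,
                       format: str = "tsv") -> None:
    path = Path(path)
    if format in ("tsv", "csv"):
        sep = "\t" if format == "tsv" else ","
        pd.DataFrame(cm.counts, index=cm.gene_ids,
                     columns=cm.sample_ids).to_csv(path, sep=sep)
    elif format == "mtx_triplet":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(cm.counts))
        path.with_suffix(".rows.txt").write_text("\n".join(cm.gene_ids) + "\n")
        path.with_suffix(".cols.txt").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")
    if labels_path is not None:
        write_labels(cm.labels, labels_path)


def read_gene_lengths(path: str | Path) -> dict[str, int]:
    """2-column (gene_id, length-in-bases) TSV; lengths must be positive."""
    df = pd.read_csv(path, sep="\t", header=None,
                     dtype={0: str}, names=["gene", "length"])
    lengths = dict(zip(df["gene"], df["length"].astype(int)))
    if any(v <= 0 for v in lengths.values()):
        raise FormatError("gene lengths must be positive")
    return lengths


def write_gene_lengths(lengths: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(list(lengths.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(g + "\n" for g in genes))


def write_score_table(table: OcclusionScoreTable, path: str | Path) -> None:
    """One row per gene: gene_id, per-class scores, mean occlusion score."""
    if not table.gene_ids:
        raise DataError("refusing to write an empty score table")
    df = pd.DataFrame(table.scores, index=pd.Index(table.gene_ids, name="gene_id"),
                      columns=table.class_labels)
    df[MEAN_SCORE_COLUMN] = table.mean_scores
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_score_table(path: str | Path) -> OcclusionScoreTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if MEAN_SCORE_COLUMN not in df.columns:
        raise FormatError(f"score table {path} lacks the mean-score column")
    classes = [c for c in df.columns if c != MEAN_SCORE_COLUMN]
    return OcclusionScoreTable(
        [str(g) for g in df.index], classes,
        df[classes].to_numpy(dtype=float),
    )


# -- model persistence --------------------------------------------------------

_META_NAME = "metadata.json"
_WEIGHTS_NAME = "weights.npz"


def save_model(model, path: str | Path) -> None:
    """Persist a fitted :class:`~geneso.classifier.LSTMClassifier`.

    The directory holds ``weights.npz`` (all layer weights) and
    ``metadata.json`` (architecture config, frozen gene order, z-score
    statistics, class labels).
    """
    from .classifier import LSTMClassifier  # local import, avoids cycle

    if not isinstance(model, LSTMClassifier):
        raise TypeError("save_model expects an LSTMClassifier")
    if not hasattr(model, "network_"):
        raise DataError("model is not fitted")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    weights = model.network_.parameter_dict()
    np.savez(path / _WEIGHTS_NAME, **weights)
    meta = {
        "format_version": 1,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "gene_ids": list(model.gene_ids_) if model.gene_ids_ is not None else None,
        "classes": [str(c) for c in model.classes_],
        "zscore": {
            "mean": model.zscore_.mean.tolist(),
            "std": model.zscore_.std.tolist(),
            "ddof": model.zscore_.ddof,
        },
        "layout": {"timesteps": model.timesteps_,
                   "features_per_step": model.features_per_step_},
        "weight_keys": sorted(weights),
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))


def load_model(path: str | Path):
    """Inverse of :func:`save_model`; validates weight/metadata consistency."""
    from ._containers import ZScoreStats
    from .classifier import LSTMClassifier
    from .nn import LSTMNetwork

    path = Path(path)
    meta_path = path / _META_NAME
    weights_path = path / _WEIGHTS_NAME
    if not meta_path.exists() or not weights_path.exists():
        raise CorruptModelError(f"model directory {path} is incomplete")
    meta = json.loads(meta_path.read_text())
    if meta.get("gene_ids") is None:
        raise CorruptModelError("model metadata lacks the frozen gene order")
    with np.load(weights_path) as npz:
        weights = {k: npz[k] for k in npz.files}
    if sorted(weights) != meta.get("weight_keys"):
        raise CorruptModelError("weight blob does not match metadata manifest")

    params = dict(meta["params"])
    if isinstance(params.get("hidden_sizes"), list):
        params["hidden_sizes"] = tuple(params["hidden_sizes"])
    model = LSTMClassifier(**params)
    model.classes_ = np.array(meta["classes"], dtype=object)
    model.gene_ids_ = list(meta["gene_ids"])
    zs = meta["zscore"]
    model.zscore_ = ZScoreStats(model.gene_ids_, np.array(zs["mean"]),
                                np.array(zs["std"]), ddof=zs["ddof"])
    model.timesteps_ = meta["layout"]["timesteps"]
    model.features_per_step_ = meta["layout"]["features_per_step"]
    try:
        model.network_ = LSTMNetwork.from_parameter_dict(weights)
    except (KeyError, ValueError) as exc:
        raise CorruptModelError(f"cannot rebuild network: {exc}") from exc
    if model.network_.n_classes != len(model.classes_):
        raise CorruptModelError("class count mismatch between weights and metadata")
    model.n_features_in_ = len(model.gene_ids_)
    return model
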