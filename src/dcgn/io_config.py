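"""Expression-matrix / label / config / report I/O and the core containers.

The universal pipeline currency is :class:`ExpressionDataset`: a samples x
genes real matrix with sample IDs, gene IDs and integer class labels coded
``0..C-1``.  Matrices travel as CSV/TSV with sample IDs in the first column
and gene IDs in the header row; configs and evaluation reports travel as
JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class LoadError(ValueError):
    """Raised when an input file violates the expected layout or contract."""


@dataclass
class ExpressionDataset:
    """Samples x genes expression matrix with aligned integer labels.

    ``labels`` are contiguous codes ``0..C-1``; ``label_names`` maps each
    code back to the original label string (lexicographic coding, so the
    mapping is a deterministic bijection).  ``synthetic_mask`` flags rows
    created by oversampling rather than observed.
    """

    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    labels: np.ndarray
    synthetic_mask: np.ndarray = None  # type: ignore[assignment]
    label_names: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.synthetic_mask is None:
            self.synthetic_mask = np.zeros(len(self.labels), dtype=bool)
        self.synthetic_mask = np.asarray(self.synthetic_mask, dtype=bool)
        if not self.label_names:
            self.label_names = [str(c) for c in range(int(self.labels.max()) + 1)] if len(self.labels) else []
        self.validate()

    def validate(self) -> None:
        n, g = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample IDs for {n} matrix rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene IDs for {g} matrix columns")
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} samples")
        if len(self.synthetic_mask) != n:
            raise ValueError("synthetic_mask length mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample IDs are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene IDs are not unique")
        if np.isnan(self.values).any():
            raise ValueError("matrix contains missing values")
        if n:
            if self.labels.min() < 0:
                raise ValueError("negative class label")
            if self.labels.max() >= len(self.label_names):
                raise ValueError("label code outside the declared classes")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.label_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, indices: Sequence[int]) -> "ExpressionDataset":
        idx = np.asarray(indices, dtype=int)
        return ExpressionDataset(
            sample_ids=[self.sample_ids[i] for i in idx],
            gene_ids=list(self.gene_ids),
            values=self.values[idx].copy(),
            labels=self.labels[idx].copy(),
            synthetic_mask=self.synthetic_mask[idx].copy(),
            label_names=list(self.label_names),
            metadata=dict(self.metadata),
        )


@dataclass
class DCGNConfig:
    """All architecture and training hyperparameters of the DCGN network.

    Defaults follow the published setting: feature-learning node counts
    1024 / 128 / 64 / 64 (FC width, conv-1 kernels, conv-2 kernels, GRU
    units per direction), classifier widths 128 / 64 / 32, batch size 256,
    Adam at learning rate 1e-3, dropout 0.6 / 0.7, gelu activation, an
    80/10/10 split and a 15% minority threshold for SMOTE.
    """

    fc_nodes: int = 1024
    conv1_kernels: int = 128
    conv2_kernels: int = 64
    kernel_size: tuple[int, int] = (3, 3)
    conv_strides: int = 2
    pool_size: tuple[int, int] = (2, 2)
    gru_units: int = 64
    classifier_nodes: tuple[int, ...] = (128, 64, 32)
    n_classes: int = 2
    dropout_rates: tuple[float, float] = (0.6, 0.7)
    batch_size: int = 256
    learning_rate: float = 1e-3
    epochs: int = 100
    early_stop_patience: int = 10
    seed: int = 0
    activation: str = "gelu_approx"
    smote_threshold: float = 0.15
    smote_k: int = 5
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    bigru_sequence_axis: str = "rows"  # or "columns"

    def __post_init__(self) -> None:
        self.kernel_size = tuple(self.kernel_size)  # type: ignore[assignment]
        self.pool_size = tuple(self.pool_size)  # type: ignore[assignment]
        self.classifier_nodes = tuple(self.classifier_nodes)  # type: ignore[assignment]
        self.dropout_rates = tuple(self.dropout_rates)  # type: ignore[assignment]
        self.split_fractions = tuple(self.split_fractions)  # type: ignore[assignment]
        self.validate()

    def validate(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError(f"split fractions {self.split_fractions} do not sum to 1")
        for r in self.dropout_rates:
            if not (0.0 <= r < 1.0):
                raise ValueError(f"dropout rate {r} outside [0, 1)")
        side = int(round(np.sqrt(self.fc_nodes)))
        if side * side != self.fc_nodes:
            raise ValueError(f"fc_nodes={self.fc_nodes} is not a perfect square")
        if not (0.0 < self.smote_threshold < 1.0):
            raise ValueError("smote_threshold must lie in (0, 1)")
        if self.smote_k < 1:
            raise ValueError("smote_k must be >= 1")
        if self.bigru_sequence_axis not in ("rows", "columns"):
            raise ValueError("bigru_sequence_axis must be 'rows' or 'columns'")
        from .activations import ACTIVATIONS

        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DCGNConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "DCGNConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _read_table(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read CSV/TSV with the first column as index; sniff the delimiter."""
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    else:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    return df


def load_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    transpose: bool = False,
    impute_missing: bool = False,
    delimiter: str | None = None,
) -> ExpressionDataset:
    """Load an expression matrix and a sample->label table into a dataset.

    The matrix file has sample IDs in the first column and gene IDs in the
    header (``transpose=True`` for gene-major files).  The labels file maps
    sample ID to a class label; labels are re-coded to ``0..C-1`` in
    lexicographic order of the original strings, and the mapping is kept on
    the returned dataset.

    Raises
    ------
    LoadError
        On non-numeric cells (with row/column coordinates), missing values
        when ``impute_missing`` is off, or sample-ID mismatches (naming the
        offending IDs).
    """
    raw = _read_table(matrix_path, delimiter)
    if transpose:
        raw = raw.T
    # locate non-numeric cells before coercing
    values = raw.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & raw.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise LoadError(
            f"non-numeric cell at row {raw.index[r]!r}, column {raw.columns[c]!r}: "
            f"{raw.iat[r, c]!r}"
        )
    if values.isna().to_numpy().any():
        if impute_missing:
            values = values.fillna(values.mean(axis=0))
        else:
            r, c = np.argwhere(values.isna().to_numpy())[0]
            raise LoadError(
                f"missing value at row {values.index[r]!r}, column "
                f"{values.columns[c]!r} (pass impute_missing=True to impute "
                "per-gene means)"
            )

    lab = _read_table(labels_path, delimiter)
    label_col = lab.columns[0]
    label_map = {str(k): str(v) for k, v in lab[label_col].items()}

    sample_ids = [str(s) for s in values.index]
    missing = [s for s in sample_ids if s not in label_map]
    if missing:
        raise LoadError(f"samples missing from the labels file: {missing}")
    extra = [s for s in label_map if s not in set(sample_ids)]
    if extra:
        raise LoadError(f"labels given for unknown samples: {extra}")

    raw_labels = [label_map[s] for s in sample_ids]
    names = sorted(set(raw_labels))
    if len(names) < 2:
        raise LoadError(f"need at least 2 classes, found {len(names)}")
    code = {name: i for i, name in enumerate(names)}
    labels = np.array([code[x] for x in raw_labels], dtype=int)

    return ExpressionDataset(
        sample_ids=sample_ids,
        gene_ids=[str(g) for g in values.columns],
        values=values.to_numpy(dtype=float),
        labels=labels,
        label_names=names,
    )


def save_expression(
    data: ExpressionDataset,
    matrix_path: str | Path,
    labels_path: str | Path,
    *,
    delimiter: str = ",",
) -> None:
    """Write a dataset back to a matrix CSV/TSV and a labels CSV/TSV."""
    df = pd.DataFrame(data.values, index=data.sample_ids, columns=data.gene_ids)
    df.index.name = "sample_id"
    df.to_csv(matrix_path, sep=delimiter)
    lab = pd.DataFrame(
        {"label": [data.label_names[c] for c in data.labels]}, index=data.sample_ids
    )
    lab.index.name = "sample_id"
    lab.to_csv(labels_path, sep=delimiter)


def write_report(report, path: str | Path) -> None:
    """Serialize an :class:`~dcgn.evaluation.EvaluationReport` to JSON."""
    d = report.to_dict()
    for v in (d["accuracy"], d["precision_weighted"], d["recall_weighted"],
              d["f1_weighted"], d["kappa"], d["hamming"]):
        if not np.isfinite(v):
            raise ValueError(f"non-finite metric in report: {v}")
    Path(path).write_text(json.dumps(d, indent=2))


def read_report(path: str | Path):
    """Read back a report written by :func:`write_report`."""
    from .evaluation import EvaluationReport

    return EvaluationReport.from_dict(json.loads(Path(path).read_text()))
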