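"""Class balancing, feature standardization and dataset splitting.

Severely imbalanced subtype labels (e.g. 150 vs 721 samples) are balanced
with SMOTE: each minority-class sample is interpolated toward one of its k
nearest same-class neighbours, ``x_new = x_i + (x_n - x_i) * r`` with
``r ~ Uniform(0,1)``.  Features are then standardized to zero mean and unit
variance using the population (divide-by-n) standard deviation, and the
data is split 80/10/10 into train/validation/test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .io_config import ExpressionDataset


@dataclass
class SmoteParams:
    """SMOTE settings: minority threshold, neighbour count, target size."""

    threshold: float = 0.15
    k: int = 5
    target_count: int | str = "majority"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError(f"threshold {self.threshold} outside (0, 1)")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if isinstance(self.target_count, str) and self.target_count != "majority":
            raise ValueError("target_count must be an int or 'majority'")


@dataclass
class StandardizationParams:
    """Per-gene mean and population standard deviation, fitted once."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.std = np.asarray(self.std, dtype=float)
        if self.mean.shape != self.std.shape:
            raise ValueError("mean and std lengths differ")
        if (self.std < 0).any():
            raise ValueError("negative standard deviation")

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"mean": self.mean.tolist(), "std": self.std.tolist()})
        )

    @classmethod
    def load(cls, path: str | Path) -> "StandardizationParams":
        d = json.loads(Path(path).read_text())
        return cls(mean=np.array(d["mean"]), std=np.array(d["std"]))


def identify_minority_classes(labels: np.ndarray, threshold: float) -> set[int]:
    """Classes whose count is strictly below ``threshold * n_samples``."""
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label vector")
    counts = np.bincount(labels)
    present = np.flatnonzero(counts)
    if len(present) < 2:
        raise ValueError("need at least 2 classes present")
    cutoff = threshold * labels.size
    return {int(c) for c in present if counts[c] < cutoff}


def _knn_same_class(x: np.ndarray, k: int) -> np.ndarray:
    """Indices (within ``x``) of the k nearest neighbours of each row,
    excluding self, Euclidean distance, ties broken by original row order."""
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")
    return order[:, :k]


def smote_oversample(data: ExpressionDataset, params: SmoteParams) -> ExpressionDataset:
    """Oversample every minority class up to ``target_count`` with SMOTE.

    Minority classes are those below ``params.threshold`` of the total.
    Original rows are kept untouched and synthetic rows are flagged in the
    returned dataset's ``synthetic_mask``.  ``k`` is clamped (with a
    warning) to class size minus one when a minority class is too small.

    Raises
    ------
    ValueError
        If a minority class has a single member (no neighbour to
        interpolate toward).
    """
    minority = identify_minority_classes(data.labels, params.threshold)
    counts = data.class_counts()
    if isinstance(params.target_count, str):
        target = int(counts.max())
    else:
        target = int(params.target_count)

    rng = np.random.default_rng(params.seed)
    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    new_ids: list[str] = []

    for c in sorted(minority):
        members = np.flatnonzero(data.labels == c)
        size = len(members)
        if size < 2:
            raise ValueError(
                f"minority class {c} has {size} sample(s); SMOTE needs >= 2"
            )
        n_new = target - size
        if n_new <= 0:
            continue
        k = params.k
        if k >= size:
            warnings.warn(
                f"SMOTE k={k} clamped to {size - 1} for class {c} (size {size})",
                stacklevel=2,
            )
            k = size - 1
        x = data.values[members]
        nn = _knn_same_class(x, k)
        for j in range(n_new):
            i = j % size  # cycle seeds so coverage is even
            x_i = x[i]
            x_n = x[nn[i, rng.integers(k)]]
            r = rng.random()
            new_rows.append(x_i + (x_n - x_i) * r)
            new_labels.append(c)
            new_ids.append(f"smote_c{c}_{j}")

    if not new_rows:
        return data.subset(np.arange(data.n_samples))

    values = np.vstack([data.values, np.array(new_rows)])
    labels = np.concatenate([data.labels, np.array(new_labels, dtype=int)])
    mask = np.concatenate(
        [data.synthetic_mask, np.ones(len(new_rows), dtype=bool)]
    )
    return ExpressionDataset(
        sample_ids=list(data.sample_ids) + new_ids,
        gene_ids=list(data.gene_ids),
        values=values,
        labels=labels,
        synthetic_mask=mask,
        label_names=list(data.label_names),
        metadata=dict(data.metadata),
    )


def random_undersample(
    data: ExpressionDataset, target_count: int, seed: int = 0
) -> ExpressionDataset:
    """Reduce every class to ``target_count`` rows, sampled without
    replacement; deterministic under ``seed``."""
    counts = data.class_counts()
    for c, n in enumerate(counts):
        if n and n < target_count:
            raise ValueError(
                f"class {data.label_names[c]!r} has {n} samples, "
                f"fewer than target {target_count}"
            )
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in range(data.n_classes):
        members = np.flatnonzero(data.labels == c)
        if len(members) == 0:
            continue
        chosen = rng.choice(members, size=target_count, replace=False)
        keep.append(np.sort(chosen))
    return data.subset(np.concatenate(keep))


def fit_standardizer(data: ExpressionDataset) -> StandardizationParams:
    """Column means and population (divide-by-n) standard deviations."""
    if data.n_samples < 2:
        raise ValueError("standardizer needs at least 2 samples")
    return StandardizationParams(
        mean=data.values.mean(axis=0),
        std=data.values.std(axis=0, ddof=0),
    )


def apply_standardizer(
    data: ExpressionDataset, params: StandardizationParams
) -> ExpressionDataset:
    """Center and scale each column; zero-variance columns map to zeros."""
    if len(params.mean) != data.n_genes:
        raise ValueError(
            f"standardizer fitted on {len(params.mean)} genes, data has "
            f"{data.n_genes}"
        )
    std = params.std.copy()
    # treat numerically-zero variance as constant (float summation noise)
    constant = std < 1e-12 * np.maximum(1.0, np.abs(params.mean))
    std[constant] = 1.0
    values = (data.values - params.mean) / std
    values[:, constant] = 0.0
    out = data.subset(np.arange(data.n_samples))
    out.values = values
    return out


def split_dataset(
    data: ExpressionDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    stratified: bool = False,
) -> tuple[ExpressionDataset, ExpressionDataset, ExpressionDataset]:
    """Random disjoint train/validation/test partition.

    Sizes use floor for train and validation, remainder to test.  With
    ``stratified`` the same rule is applied per class so label proportions
    carry over to rounding.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions {fractions} do not sum to 1")
    rng = np.random.default_rng(seed)
    f_train, f_val, _ = fractions

    def three_way(idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = rng.permutation(idx)
        n = len(idx)
        n_train = int(np.floor(n * f_train))
        n_val = int(np.floor(n * f_val))
        return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]

    if stratified:
        parts: list[list[np.ndarray]] = [[], [], []]
        for c in range(data.n_classes):
            members = np.flatnonzero(data.labels == c)
            if len(members) == 0:
                continue
            for part, chunk in zip(parts, three_way(members)):
                part.append(chunk)
        splits = tuple(np.sort(np.concatenate(p)) for p in parts)
    else:
        splits = three_way(np.arange(data.n_samples))

    for name, s in zip(("train", "validation", "test"), splits):
        if len(s) == 0:
            raise ValueError(f"{name} partition would be empty")
    return tuple(data.subset(s) for s in splits)  # type: ignore[return-value]
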