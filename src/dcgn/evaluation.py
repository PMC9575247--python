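"""Multiclass evaluation: confusion matrix, weighted precision/recall/F1,
Cohen's kappa and Hamming distance.

Weighted averaging multiplies each class's one-vs-rest precision/recall by
the class's share of samples.  ``mode="paper_literal"`` additionally
divides the weighted sums by the number of classes L, which preserves a
formula variant some publications print; under it a perfect classifier
scores 1/L, so the standard weighted average is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


def confusion_matrix(truth: np.ndarray, pred: np.ndarray, n_classes: int) -> np.ndarray:
    """C x C count matrix; rows are true classes, columns predictions."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(pred, dtype=int)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size and (
        truth.min() < 0 or truth.max() >= n_classes
        or pred.min() < 0 or pred.max() >= n_classes
    ):
        raise ValueError(f"labels outside 0..{n_classes - 1}")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (truth, pred), 1)
    return cm


def weighted_prf(
    confusion: np.ndarray, mode: str = "standard"
) -> tuple[float, float, float]:
    """Weighted precision, recall and their harmonic-mean F1.

    Per class i: precision_i = diag_i / column-sum_i (0 when the class is
    never predicted, with a warning), recall_i = diag_i / row-sum_i, and
    weight w_i = row-sum_i / n.
    """
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    if n <= 0:
        raise ValueError("confusion matrix sums to zero")
    if mode not in ("standard", "paper_literal"):
        raise ValueError(f"unknown mode {mode!r}")
    diag = np.diag(cm)
    colsum = cm.sum(axis=0)
    rowsum = cm.sum(axis=1)
    if ((colsum == 0) & (rowsum > 0)).any():
        warnings.warn(
            "some classes are never predicted; their precision is set to 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        precision_i = np.where(colsum > 0, diag / np.where(colsum > 0, colsum, 1), 0.0)
        recall_i = np.where(rowsum > 0, diag / np.where(rowsum > 0, rowsum, 1), 0.0)
    w = rowsum / n
    p = float((precision_i * w).sum())
    r = float((recall_i * w).sum())
    if mode == "paper_literal":
        l_classes = cm.shape[0]
        p /= l_classes
        r /= l_classes
    f1 = 0.0 if p + r == 0 else 2.0 * p * r / (p + r)
    return p, r, f1


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement (P0 - Pe) / (1 - Pe).

    P0 is observed accuracy (trace / n); Pe sums, over classes, the product
    of true and predicted marginal counts, divided by n squared.
    """
    cm = np.asarray(confusion, dtype=float)
    n = cm.sum()
    if n <= 0:
        raise ValueError("confusion matrix sums to zero")
    p0 = np.trace(cm) / n
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    if pe == 1.0:
        raise ValueError(
            "chance agreement Pe == 1 (all mass in one marginal cell); "
            "kappa is undefined"
        )
    return float((p0 - pe) / (1.0 - pe))


def hamming_distance(truth: np.ndarray, pred: np.ndarray) -> float:
    """Fraction of samples whose predicted label differs from the truth."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size == 0:
        raise ValueError("empty label vectors")
    return float((truth != pred).mean())


@dataclass
class EvaluationReport:
    """Confusion matrix plus the five scalar metrics and per-class detail."""

    confusion: np.ndarray
    accuracy: float
    precision_weighted: float
    recall_weighted: float
    f1_weighted: float
    kappa: float
    hamming: float
    per_class: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision_weighted": self.precision_weighted,
            "recall_weighted": self.recall_weighted,
            "f1_weighted": self.f1_weighted,
            "kappa": self.kappa,
            "hamming": self.hamming,
            "per_class": self.per_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(
            confusion=np.array(d["confusion"], dtype=int),
            accuracy=d["accuracy"],
            precision_weighted=d["precision_weighted"],
            recall_weighted=d["recall_weighted"],
            f1_weighted=d["f1_weighted"],
            kappa=d["kappa"],
            hamming=d["hamming"],
            per_class=d.get("per_class", {}),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvaluationReport):
            return NotImplemented
        return (
            np.array_equal(self.confusion, other.confusion)
            and np.allclose(
                [self.accuracy, self.precision_weighted, self.recall_weighted,
                 self.f1_weighted, self.kappa, self.hamming],
                [other.accuracy, other.precision_weighted, other.recall_weighted,
                 other.f1_weighted, other.kappa, other.hamming],
            )
        )


def report_from_predictions(
    truth: np.ndarray, pred: np.ndarray, n_classes: int, mode: str = "standard"
) -> EvaluationReport:
    """Assemble the full report from truth/prediction vectors."""
    cm = confusion_matrix(truth, pred, n_classes)
    n = cm.sum()
    accuracy = float(np.trace(cm) / n)
    p, r, f1 = weighted_prf(cm, mode=mode)
    diag = np.diag(cm)
    colsum = cm.sum(axis=0)
    rowsum = cm.sum(axis=1)
    per_class = {
        str(c): {
            "precision": float(diag[c] / colsum[c]) if colsum[c] else 0.0,
            "recall": float(diag[c] / rowsum[c]) if rowsum[c] else 0.0,
            "support": float(rowsum[c] / n),
        }
        for c in range(n_classes)
    }
    return EvaluationReport(
        confusion=cm,
        accuracy=accuracy,
        precision_weighted=p,
        recall_weighted=r,
        f1_weighted=f1,
        kappa=cohens_kappa(cm),
        hamming=hamming_distance(truth, pred),
        per_class=per_class,
    )


def evaluate(model, data, mode: str = "standard") -> EvaluationReport:
    """Score a dataset with a :class:`~dcgn.dcgn_model.TrainedDCGN`.

    The model's stored standardization parameters are applied to the raw
    values, predictions are the argmax over logits (ties to the lowest
    class index), and the full metric suite is assembled.
    """
    if data.n_genes != model.model.n_genes:
        raise ValueError(
            f"model expects {model.model.n_genes} genes, data has {data.n_genes}"
        )
    pred = model.predict(data.values)
    return report_from_predictions(
        data.labels, pred, model.config.n_classes, mode=mode
    )
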