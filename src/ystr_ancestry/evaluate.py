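"""Evaluation surfaces: confusion matrix, per-class report,
misclassification summary, per-population discriminative-allele
rankings, and probability-calibration diagnostics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import AlleleVocabulary
from .preprocess import LabelEncoding


class EvaluationError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    """k x k counts; rows = true class, columns = predicted class."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (len(self.classes), len(self.classes)) or np.any(c < 0):
            raise EvaluationError("counts must be a nonnegative k x k matrix")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(
    true_labels, predicted_labels, encoding: LabelEncoding
) -> ConfusionMatrix:
    """Tally counts[i][j] = #{samples with true class i predicted as j}.

    Labels may be integer indices or population names.
    """
    def as_idx(values):
        out = []
        for v in values:
            if isinstance(v, str):
                out.append(encoding.to_int(v))
            else:
                v = int(v)
                if not 0 <= v < encoding.k:
                    raise EvaluationError(f"label index {v} outside encoding")
                out.append(v)
        return np.asarray(out, dtype=np.int64)

    t = as_idx(true_labels)
    p = as_idx(predicted_labels)
    if t.shape != p.shape:
        raise EvaluationError("true and predicted labels differ in length")
    k = encoding.k
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    return ConfusionMatrix(classes=encoding.classes, counts=counts)


@dataclass
class ClassReport:
    """Per-class precision/recall/F1 plus overall, weighted and macro
    aggregates. Weighted recall equals overall accuracy by construction."""

    classes: tuple[str, ...]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "precision": self.precision,
                "recall": self.recall,
                "f1": self.f1,
                "support": self.support,
            },
            index=self.classes,
        )
        df.loc["macro avg"] = [*(self.macro[m] for m in ("precision", "recall", "f1")),
                               self.support.sum()]
        df.loc["weighted avg"] = [*(self.weighted[m] for m in ("precision", "recall", "f1")),
                                  self.support.sum()]
        return df

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                c: {
                    "precision": float(self.precision[i]),
                    "recall": float(self.recall[i]),
                    "f1": float(self.f1[i]),
                    "support": int(self.support[i]),
                }
                for i, c in enumerate(self.classes)
            },
            "macro": self.macro,
            "weighted": self.weighted,
        }


def report(matrix: ConfusionMatrix) -> ClassReport:
    """Compute the per-class metric table from a confusion matrix.

    Zero denominators yield 0 with a warning (so reports stay total on
    classes absent from truth or predictions).
    """
    c = matrix.counts
    total = c.sum()
    if total == 0:
        raise EvaluationError("empty confusion matrix")
    tp = np.diag(c).astype(float)
    support = c.sum(axis=1).astype(float)          # true counts
    predicted = c.sum(axis=0).astype(float)        # predicted counts

    def safe_div(num, den, what):
        out = np.zeros_like(num)
        nz = den > 0
        out[nz] = num[nz] / den[nz]
        if np.any(~nz):
            warnings.warn(
                f"{what} undefined for {int((~nz).sum())} class(es); reported as 0",
                RuntimeWarning, stacklevel=3,
            )
        return out

    precision = safe_div(tp, predicted, "precision")
    recall = safe_div(tp, support, "recall")
    denom = precision + recall
    f1 = np.where(denom > 0, 2 * precision * recall / np.where(denom > 0, denom, 1), 0.0)
    accuracy = float(tp.sum() / total)
    w = support / support.sum()
    return ClassReport(
        classes=matrix.classes,
        precision=precision,
        recall=recall,
        f1=f1,
        support=support.astype(int),
        accuracy=accuracy,
        macro={
            "precision": float(precision.mean()),
            "recall": float(recall.mean()),
            "f1": float(f1.mean()),
        },
        weighted={
            "precision": float((w * precision).sum()),
            "recall": float((w * recall).sum()),
            "f1": float((w * f1).sum()),
        },
    )


def misclassification_summary(
    matrix: ConfusionMatrix, top_n: int = 5
) -> list[tuple[str, str, int]]:
    """Largest off-diagonal cells as (true, predicted, count), sorted by
    count descending, ties by name order; zero cells omitted."""
    if top_n < 1:
        raise EvaluationError("top_n must be >= 1")
    cells = [
        (matrix.classes[i], matrix.classes[j], int(matrix.counts[i, j]))
        for i in range(len(matrix.classes))
        for j in range(len(matrix.classes))
        if i != j and matrix.counts[i, j] > 0
    ]
    cells.sort(key=lambda c: (-c[2], c[0], c[1]))
    return cells[:top_n]


def importance_ranking(
    experts, vocab: AlleleVocabulary, feature_std: np.ndarray | None = None
) -> dict[str, list[tuple[str, float]]]:
    """Per-population discriminative-feature ranking from each expert.

    Tree ensembles contribute impurity-based importances; linear models
    contribute |coefficient| x feature standard deviation (the
    standardized effect size). Scores are normalized to max 1 per
    population and sorted descending, named ``LOCUS_ALLELE``.
    """
    names = vocab.feature_names
    out: dict[str, list[tuple[str, float]]] = {}
    for e in experts:
        est = e.estimator
        if hasattr(est, "feature_importances_"):
            raw = np.asarray(est.feature_importances_, dtype=float)
        elif hasattr(est, "coef_"):
            raw = np.abs(np.asarray(est.coef_, dtype=float).ravel())
            if feature_std is not None:
                raw = raw * np.asarray(feature_std, dtype=float)
        else:
            raise EvaluationError(
                f"expert {e.population!r} ({e.spec.algorithm}) exposes no "
                "feature-importance notion"
            )
        if raw.shape[0] != len(names):
            raise EvaluationError("importance vector does not match vocabulary")
        top = raw.max()
        scores = raw / top if top > 0 else raw
        order = np.argsort(-scores, kind="stable")
        out[e.population] = [(names[i], float(scores[i])) for i in order]
    return out


def calibration_diagnostics(
    probs, labels, n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """Expected calibration error with an equal-width-bin reliability table.

    ``probs`` are predicted positive-class (or predicted-class
    confidence) values in [0, 1]; ``labels`` are the corresponding binary
    outcomes (1 = event / correct).
    """
    if n_bins < 1:
        raise EvaluationError("n_bins must be >= 1")
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape or p.ndim != 1 or p.size == 0:
        raise EvaluationError("probs and labels must be equal-length non-empty 1-D")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, n_bins - 1)
    rows, ece = [], 0.0
    for b in range(n_bins):
        mask = idx == b
        n = int(mask.sum())
        conf = float(p[mask].mean()) if n else np.nan
        acc = float(y[mask].mean()) if n else np.nan
        if n:
            ece += (n / p.size) * abs(acc - conf)
        rows.append({"bin_low": edges[b], "bin_high": edges[b + 1],
                     "n": n, "mean_confidence": conf, "empirical_rate": acc})
    return float(ece), pd.DataFrame(rows)
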