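"""One-vs-rest calibrated experts fused by attention into a meta-network.

The core method. For each of the k populations a binary expert is
trained (that population vs the rest), its raw scores are Platt-
calibrated on out-of-fold predictions, and the k calibrated
probabilities are combined by attention weights

    final_prediction = sum_i attention_weight_i * classifier_probability_i

where the weights are a softmax over each expert's validation balanced
accuracy plus a normalized mutual-information score. The per-expert
weighted terms (and their sum) feed a small fully-connected meta-network
that outputs the final k-class probabilities.

The public surface follows the Model/Results convention:
``OvRAttentionModel(table, ...).fit()`` returns an
:class:`OvRAttentionResults` carrying the experts, calibration and
attention parameters, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold

from .base import BinaryClassifierSpec
from .calibration import CalibrationParams, platt_apply, platt_fit
from .data import HaplotypeTable
from .features import (
    AlleleVocabulary,
    FeatureMatrix,
    binary_mi_per_column,
    build_vocabulary,
    label_entropy,
    one_hot_encode,
    select_one_per_marker,
)
from .metanet import MetaNetworkConfig, predict_proba_full, train_meta_network
from .preprocess import LabelEncoding, encode_labels
from .tuning import cv_balanced_accuracy, tune_hyperparameters


class FitError(ValueError):
    pass


def count_classifiers(k: int, strategy: str) -> int:
    """Number of binary classifiers: k for OvR, k(k-1)/2 for OvO."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if strategy == "ovr":
        return k
    if strategy == "ovo":
        return k * (k - 1) // 2
    raise ValueError("strategy must be 'ovr' or 'ovo'")


@dataclass(frozen=True)
class AttentionWeights:
    """Nonnegative per-expert weights summing to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("attention weights must be a probability vector")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class OvRPrediction:
    """Calibrated positive-class probabilities, one column per expert.

    The complementary negative-class probability is implicit (1 - p).
    """

    probs: np.ndarray  # (n_samples, k) in [0, 1]
    classifier_order: tuple[str, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != len(self.classifier_order):
            raise ValueError("probs and classifier_order are misaligned")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.probs = p


def compute_attention_weights(
    per_expert_metrics, mi_scores, temperature: float = 1.0
) -> AttentionWeights:
    """softmax((metric + mi) / temperature) across experts."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    m = np.asarray(per_expert_metrics, dtype=float)
    mi = np.asarray(mi_scores, dtype=float)
    if m.shape != mi.shape or m.ndim != 1 or m.size < 1:
        raise ValueError("metric and MI vectors must be equal-length 1-D")
    z = (m + mi) / temperature
    z = z - z.max()  # overflow-safe
    e = np.exp(z)
    return AttentionWeights(weights=e / e.sum())


def fuse(prediction: OvRPrediction, weights: AttentionWeights) -> np.ndarray:
    """Per sample: the k attention-weighted expert probabilities plus
    their sum (the scalar of the weighted-summation rule) -> (n, k+1)."""
    if len(weights) != prediction.probs.shape[1]:
        raise ValueError(
            f"{len(weights)} weights for {prediction.probs.shape[1]} classifiers"
        )
    terms = prediction.probs * weights.weights[np.newaxis, :]
    return np.hstack([terms, terms.sum(axis=1, keepdims=True)])


@dataclass
class OvRExpert:
    """One fitted population expert: spec, estimator, calibration, metrics."""

    population: str
    spec: BinaryClassifierSpec
    estimator: object
    calibration: CalibrationParams
    oof_balanced_accuracy: float
    mi_score: float

    def calibrated_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.estimator.predict_proba(X)[:, 1]
        return platt_apply(self.calibration, raw)


def _oof_scores(
    spec: BinaryClassifierSpec, X: np.ndarray, y_bin: np.ndarray,
    n_folds: int, seed: int,
) -> np.ndarray:
    """Out-of-fold positive-class scores under stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y_bin))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in skf.split(X, y_bin):
            est = spec.build()
            est.fit(X[tr], y_bin[tr])
            oof[te] = est.predict_proba(X[te])[:, 1]
    return oof


def fit_ovr(
    X: np.ndarray,
    labels: np.ndarray,
    encoding: LabelEncoding,
    specs: dict[str, BinaryClassifierSpec],
    calibration_folds: int = 3,
    seed: int = 0,
) -> tuple[list[OvRExpert], np.ndarray]:
    """Fit k calibrated one-vs-rest experts.

    Returns the experts (panel order = encoding order) and the matrix of
    out-of-fold calibrated probabilities used for attention weighting and
    leak-free meta-network training.
    """
    y = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    k = encoding.k
    if k < 2:
        raise FitError("need at least 2 classes")
    present = set(np.unique(y).tolist())
    for i, name in enumerate(encoding.classes):
        if i not in present:
            raise FitError(f"class {name!r} absent from training data")

    experts: list[OvRExpert] = []
    oof_cal = np.zeros((len(y), k))
    for i, name in enumerate(encoding.classes):
        y_bin = (y == i).astype(int)
        spec = specs[name]
        oof_raw = _oof_scores(spec, X, y_bin, calibration_folds, seed + i)
        cal = platt_fit(oof_raw, y_bin, n_folds=calibration_folds)
        oof_p = platt_apply(cal, oof_raw)
        oof_cal[:, i] = oof_p
        bal_acc = balanced_accuracy_score(y_bin, (oof_p >= 0.5).astype(int))
        # normalized MI of the single most informative feature vs this
        # expert's binary target, in [0, 1]
        h_bin = max(label_entropy(y_bin), 1e-12)
        mi_best = float(binary_mi_per_column(X, y_bin).max())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = spec.build()
            est.fit(X, y_bin)
        experts.append(
            OvRExpert(
                population=name,
                spec=spec,
                estimator=est,
                calibration=cal,
                oof_balanced_accuracy=float(bal_acc),
                mi_score=float(mi_best / h_bin),
            )
        )
    return experts, oof_cal


class OvRAttentionModel:
    """One-vs-rest attention-ensemble classifier for Y-STR haplotypes.

    Parameters
    ----------
    table
        Complete, labeled training table (run the preprocessing pipeline
        first; missing calls raise at encoding time).
    specs
        Optional map population -> :class:`BinaryClassifierSpec`. When
        omitted, each expert's family/hyperparameters are chosen by the
        Bayesian tuner over ``tune_algorithms`` with ``tune_budget``
        evaluations per family.
    feature_mode
        ``"full"`` (default) keeps the whole one-hot matrix;
        ``"one-per-marker"`` applies the per-locus mutual-information
        selector (sensitivity-analysis mode).
    """

    def __init__(
        self,
        table: HaplotypeTable,
        *,
        specs: dict[str, BinaryClassifierSpec] | None = None,
        tune_algorithms: tuple[str, ...] = ("logistic_regression",),
        tune_budget: int = 8,
        tune_folds: int = 3,
        calibration_folds: int = 3,
        temperature: float = 1.0,
        meta_config: MetaNetworkConfig | None = None,
        feature_mode: str = "full",
        vocab: AlleleVocabulary | None = None,
        seed: int = 0,
    ) -> None:
        if feature_mode not in ("full", "one-per-marker"):
            raise ValueError("feature_mode must be 'full' or 'one-per-marker'")
        self.table = table
        self.vocab = vocab
        self.specs = specs
        self.tune_algorithms = tune_algorithms
        self.tune_budget = tune_budget
        self.tune_folds = tune_folds
        self.calibration_folds = calibration_folds
        self.temperature = temperature
        self.meta_config = meta_config or MetaNetworkConfig(seed=seed)
        self.feature_mode = feature_mode
        self.seed = seed

    @classmethod
    def from_table(cls, table: HaplotypeTable, **kwargs) -> "OvRAttentionModel":
        return cls(table, **kwargs)

    def _resolve_specs(
        self, X: np.ndarray, y: np.ndarray, encoding: LabelEncoding
    ) -> dict[str, BinaryClassifierSpec]:
        if self.specs is not None:
            missing = [c for c in encoding.classes if c not in self.specs]
            if missing:
                raise FitError(f"no spec for classes: {missing}")
            return self.specs
        resolved: dict[str, BinaryClassifierSpec] = {}
        for i, name in enumerate(encoding.classes):
            y_bin = (y == i).astype(int)
            best_spec, best_score = None, -np.inf
            for algo in self.tune_algorithms:
                spec = tune_hyperparameters(
                    X, y_bin, algo,
                    n_folds=self.tune_folds,
                    budget=self.tune_budget,
                    seed=self.seed + i,
                )
                score = cv_balanced_accuracy(spec, X, y_bin, self.tune_folds, self.seed + i)
                if score > best_score:
                    best_spec, best_score = spec, score
            resolved[name] = best_spec
        return resolved

    def fit(self) -> "OvRAttentionResults":
        encoding = encode_labels(self.table)
        if encoding.k < 2:
            raise FitError("need at least 2 populations to fit")
        vocab = self.vocab or build_vocabulary(self.table)
        fm = one_hot_encode(self.table, vocab)
        y = encoding.encode(self.table.populations)
        if self.feature_mode == "one-per-marker":
            fm, vocab = select_one_per_marker(fm, y, vocab)
        X = fm.values.astype(float)

        specs = self._resolve_specs(X, y, encoding)
        experts, oof_cal = fit_ovr(
            X, y, encoding, specs,
            calibration_folds=self.calibration_folds, seed=self.seed,
        )
        attention = compute_attention_weights(
            [e.oof_balanced_accuracy for e in experts],
            [e.mi_score for e in experts],
            self.temperature,
        )
        # meta-network is trained on out-of-fold fused features so it
        # never sees resubstitution probabilities (stacking discipline)
        fused = fuse(
            OvRPrediction(probs=oof_cal, classifier_order=encoding.classes),
            attention,
        )
        meta = train_meta_network(fused, y, self.meta_config)
        return OvRAttentionResults(
            model=self,
            encoding=encoding,
            vocab=vocab,
            experts=experts,
            attention=attention,
            meta_net=meta,
            feature_std=X.std(axis=0),
            n_train=len(y),
        )


@dataclass
class OvRAttentionResults:
    """Fitted one-vs-rest attention ensemble."""

    model: OvRAttentionModel
    encoding: LabelEncoding
    vocab: AlleleVocabulary
    experts: list[OvRExpert]
    attention: AttentionWeights
    meta_net: object
    feature_std: np.ndarray
    n_train: int

    @property
    def k(self) -> int:
        return self.encoding.k

    @property
    def n_classifiers(self) -> int:
        return len(self.experts)

    def _encode(self, table: HaplotypeTable, on_unseen: str = "error") -> np.ndarray:
        fm = one_hot_encode(table, self.vocab, on_unseen=on_unseen)
        return fm.values.astype(float)

    def ovr_probabilities(
        self, table: HaplotypeTable, *, on_unseen: str = "error"
    ) -> OvRPrediction:
        """Calibrated per-expert positive-class probabilities."""
        X = self._encode(table, on_unseen)
        probs = np.column_stack([e.calibrated_proba(X) for e in self.experts])
        return OvRPrediction(probs=probs, classifier_order=self.encoding.classes)

    def predict_proba(
        self, table: HaplotypeTable, *, on_unseen: str = "error"
    ) -> np.ndarray:
        """Final k-class probabilities from the meta-network."""
        pred = self.ovr_probabilities(table, on_unseen=on_unseen)
        fused = fuse(pred, self.attention)
        return predict_proba_full(self.meta_net, fused, self.k)

    def predict(self, table: HaplotypeTable, *, on_unseen: str = "error") -> list[str]:
        """Predicted population names (argmax; ties -> lowest class index)."""
        probs = self.predict_proba(table, on_unseen=on_unseen)
        return [self.encoding.to_name(int(i)) for i in np.argmax(probs, axis=1)]

    def predict_report(
        self, table: HaplotypeTable, top_n: int = 2, *, on_unseen: str = "error"
    ) -> pd.DataFrame:
        """Probabilistic guidance per sample: predicted class plus the
        top-``top_n`` classes with their probabilities."""
        probs = self.predict_proba(table, on_unseen=on_unseen)
        rows = []
        for sid, p in zip(table.sample_ids, probs):
            order = np.argsort(-p, kind="stable")
            row = {"SampleID": sid, "Predicted": self.encoding.to_name(int(order[0]))}
            for r in range(min(top_n, self.k)):
                row[f"Top{r + 1}"] = self.encoding.to_name(int(order[r]))
                row[f"Top{r + 1}_prob"] = float(p[order[r]])
            for i, name in enumerate(self.encoding.classes):
                row[f"P_{name}"] = float(p[i])
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable per-expert table: family, validation balanced
        accuracy, normalized MI, attention weight, calibration params."""
        lines = [
            "One-vs-Rest attention ensemble",
            f"  populations: {self.k}   experts: {self.n_classifiers}   "
            f"train samples: {self.n_train}   features: {len(self.vocab)}",
            "",
            f"{'population':<14}{'algorithm':<22}{'bal.acc':>8}{'MI':>7}"
            f"{'attn':>7}{'A':>9}{'B':>9}",
        ]
        for e, w in zip(self.experts, self.attention.weights):
            lines.append(
                f"{e.population:<14}{e.spec.algorithm:<22}"
                f"{e.oof_balanced_accuracy:>8.3f}{e.mi_score:>7.3f}{w:>7.3f}"
                f"{e.calibration.A:>9.3f}{e.calibration.B:>9.3f}"
            )
        return "\n".join(lines)
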