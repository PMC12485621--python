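"""One-vs-one stacking comparator.

One Platt-calibrated binary classifier per unordered population pair
(k(k-1)/2 in total), each trained only on the samples of its two
classes. The calibrated pairwise probabilities form the meta-feature
vector of a stacking combiner with the same fully-connected design as
the one-vs-rest meta-network. The per-pair held-out accuracy matrix is
the architecture's diagnostic surface: pairs with admixture-style
overlap show up as its minimum off-diagonal entries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning

from .base import BinaryClassifierSpec
from .calibration import CalibrationParams, platt_apply, platt_fit
from .data import HaplotypeTable
from .features import AlleleVocabulary, build_vocabulary, one_hot_encode, select_one_per_marker
from .metanet import MetaNetworkConfig, predict_proba_full, train_meta_network
from .ovr import FitError, _oof_scores, count_classifiers
from .preprocess import LabelEncoding, encode_labels


@dataclass
class PairExpert:
    """Binary classifier for one unordered class pair (i < j).

    The positive class is the higher-indexed class j, so the calibrated
    probability reads "P(class j | sample is i or j)".
    """

    pair: tuple[int, int]
    spec: BinaryClassifierSpec
    estimator: object
    calibration: CalibrationParams
    n_train: int

    def calibrated_proba(self, X: np.ndarray) -> np.ndarray:
        raw = self.estimator.predict_proba(X)[:, 1]
        return platt_apply(self.calibration, raw)


@dataclass
class PairwiseAccuracyMatrix:
    """Symmetric k x k held-out pair accuracies; diagonal undefined (NaN),
    as are pairs with no test data."""

    classes: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.classes), len(self.classes)):
            raise ValueError("matrix shape does not match class count")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("pairwise matrix must be symmetric")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.classes, columns=self.classes)

    def min_pair(self) -> tuple[str, str] | None:
        """The off-diagonal pair with the lowest defined accuracy."""
        best, best_v = None, np.inf
        k = len(self.classes)
        for i in range(k):
            for j in range(i + 1, k):
                v = self.values[i, j]
                if np.isfinite(v) and v < best_v:
                    best, best_v = (self.classes[i], self.classes[j]), v
        return best


def fit_ovo(
    X: np.ndarray,
    labels: np.ndarray,
    encoding: LabelEncoding,
    specs: dict[tuple[int, int], BinaryClassifierSpec] | BinaryClassifierSpec,
    calibration_folds: int = 3,
    seed: int = 0,
) -> list[PairExpert]:
    """Fit the k(k-1)/2 calibrated pairwise classifiers.

    ``specs`` may be one spec applied to every pair or a map keyed by the
    (i, j) index pair. Each pair model sees only its two classes'
    samples.
    """
    y = np.asarray(labels)
    X = np.asarray(X, dtype=float)
    k = encoding.k
    if k < 2:
        raise FitError("need at least 2 classes")
    experts: list[PairExpert] = []
    for idx, (i, j) in enumerate(combinations(range(k), 2)):
        mask = (y == i) | (y == j)
        if not np.any(y == i) or not np.any(y == j):
            raise FitError(
                f"pair ({encoding.to_name(i)}, {encoding.to_name(j)}) lacks data"
            )
        Xp, yp = X[mask], (y[mask] == j).astype(int)
        n_min = min(int((yp == 0).sum()), int((yp == 1).sum()))
        if n_min < calibration_folds:
            raise FitError(
                f"pair ({encoding.to_name(i)}, {encoding.to_name(j)}): "
                f"{n_min} samples in the smaller class, need >= {calibration_folds}"
            )
        spec = specs if isinstance(specs, BinaryClassifierSpec) else specs[(i, j)]
        oof = _oof_scores(spec, Xp, yp, calibration_folds, seed + idx)
        cal = platt_fit(oof, yp, n_folds=calibration_folds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            est = spec.build()
            est.fit(Xp, yp)
        experts.append(
            PairExpert(pair=(i, j), spec=spec, estimator=est,
                       calibration=cal, n_train=int(mask.sum()))
        )
    return experts


def pairwise_features(experts: list[PairExpert], X: np.ndarray) -> np.ndarray:
    """Calibrated pairwise probabilities as stacking meta-features."""
    return np.column_stack([e.calibrated_proba(X) for e in experts])


def pairwise_accuracy(
    experts: list[PairExpert],
    X_test: np.ndarray,
    y_test: np.ndarray,
    encoding: LabelEncoding,
) -> PairwiseAccuracyMatrix:
    """Held-out accuracy of each pair classifier on its own two classes.

    Pairs with no test samples from either class get NaN.
    """
    y = np.asarray(y_test)
    k = encoding.k
    vals = np.full((k, k), np.nan)
    for e in experts:
        i, j = e.pair
        mask = (y == i) | (y == j)
        if not np.any(mask):
            continue
        p = e.calibrated_proba(np.asarray(X_test, dtype=float)[mask])
        pred_j = p >= 0.5
        truth_j = y[mask] == j
        acc = float(np.mean(pred_j == truth_j))
        vals[i, j] = vals[j, i] = acc
    return PairwiseAccuracyMatrix(classes=encoding.classes, values=vals)


class OvOStackingModel:
    """One-vs-one stacking classifier over the same feature space as the
    one-vs-rest model, for apples-to-apples architecture comparison."""

    def __init__(
        self,
        table: HaplotypeTable,
        *,
        spec: BinaryClassifierSpec | None = None,
        calibration_folds: int = 3,
        meta_config: MetaNetworkConfig | None = None,
        feature_mode: str = "full",
        vocab: AlleleVocabulary | None = None,
        seed: int = 0,
    ) -> None:
        if feature_mode not in ("full", "one-per-marker"):
            raise ValueError("feature_mode must be 'full' or 'one-per-marker'")
        self.table = table
        self.vocab = vocab
        self.spec = spec or BinaryClassifierSpec("logistic_regression", seed=seed)
        self.calibration_folds = calibration_folds
        self.meta_config = meta_config or MetaNetworkConfig(seed=seed)
        self.feature_mode = feature_mode
        self.seed = seed

    @classmethod
    def from_table(cls, table: HaplotypeTable, **kwargs) -> "OvOStackingModel":
        return cls(table, **kwargs)

    def fit(self) -> "OvOStackingResults":
        encoding = encode_labels(self.table)
        vocab = self.vocab or build_vocabulary(self.table)
        fm = one_hot_encode(self.table, vocab)
        y = encoding.encode(self.table.populations)
        if self.feature_mode == "one-per-marker":
            fm, vocab = select_one_per_marker(fm, y, vocab)
        X = fm.values.astype(float)

        experts = fit_ovo(
            X, y, encoding, self.spec,
            calibration_folds=self.calibration_folds, seed=self.seed,
        )
        # leak-free stacking: combiner trained on out-of-fold pairwise
        # probabilities, evaluated on refit experts at predict time
        meta_X = np.zeros((len(y), len(experts)))
        for col, e in enumerate(experts):
            i, j = e.pair
            mask = (y == i) | (y == j)
            Xp, yp = X[mask], (y[mask] == j).astype(int)
            oof = _oof_scores(e.spec, Xp, yp, self.calibration_folds, self.seed + col)
            meta_X[mask, col] = platt_apply(e.calibration, oof)
            # samples outside the pair get the expert's refit probability
            if np.any(~mask):
                meta_X[~mask, col] = e.calibrated_proba(X[~mask])
        meta = train_meta_network(meta_X, y, self.meta_config)
        return OvOStackingResults(
            model=self, encoding=encoding, vocab=vocab,
            experts=experts, meta_net=meta, n_train=len(y),
        )


@dataclass
class OvOStackingResults:
    """Fitted one-vs-one stacking ensemble."""

    model: OvOStackingModel
    encoding: LabelEncoding
    vocab: AlleleVocabulary
    experts: list[PairExpert]
    meta_net: object
    n_train: int

    @property
    def k(self) -> int:
        return self.encoding.k

    @property
    def n_classifiers(self) -> int:
        return len(self.experts)

    def _encode(self, table: HaplotypeTable, on_unseen: str = "error") -> np.ndarray:
        return one_hot_encode(table, self.vocab, on_unseen=on_unseen).values.astype(float)

    def predict_proba(
        self, table: HaplotypeTable, *, on_unseen: str = "error"
    ) -> np.ndarray:
        X = self._encode(table, on_unseen)
        meta_X = pairwise_features(self.experts, X)
        return predict_proba_full(self.meta_net, meta_X, self.k)

    def predict(self, table: HaplotypeTable, *, on_unseen: str = "error") -> list[str]:
        probs = self.predict_proba(table, on_unseen=on_unseen)
        return [self.encoding.to_name(int(i)) for i in np.argmax(probs, axis=1)]

    def pairwise_accuracy(
        self, table: HaplotypeTable, *, on_unseen: str = "error"
    ) -> PairwiseAccuracyMatrix:
        """Symmetric per-pair accuracy matrix on held-out data."""
        X = self._encode(table, on_unseen)
        y = self.encoding.encode(table.populations)
        return pairwise_accuracy(self.experts, X, y, self.encoding)

    def summary(self) -> str:
        lines = [
            "One-vs-One stacking ensemble",
            f"  populations: {self.k}   pair classifiers: {self.n_classifiers}"
            f"   train samples: {self.n_train}   features: {len(self.vocab)}",
            "",
            f"{'pair':<30}{'algorithm':<22}{'n_train':>8}",
        ]
        for e in self.experts:
            i, j = e.pair
            name = f"{self.encoding.to_name(i)} vs {self.encoding.to_name(j)}"
            lines.append(f"{name:<30}{e.spec.algorithm:<22}{e.n_train:>8}")
        return "\n".join(lines)
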