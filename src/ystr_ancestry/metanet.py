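"""Fully-connected meta-network over fused expert outputs.

A small multilayer perceptron (ReLU hidden layers, softmax output,
cross-entropy loss, backprop via Adam) maps the attention-fused expert
probabilities to final k-class probabilities. Deterministic given the
config seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier


class MetaNetworkError(ValueError):
    pass


@dataclass(frozen=True)
class MetaNetworkConfig:
    hidden_sizes: tuple[int, ...] = (64, 32)
    epochs: int = 300
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise MetaNetworkError("hidden sizes must be positive")
        if self.epochs <= 0 or self.learning_rate <= 0:
            raise MetaNetworkError("epochs and learning_rate must be positive")
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))

    def to_dict(self) -> dict:
        return {
            "hidden_sizes": list(self.hidden_sizes),
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }


def train_meta_network(
    fused: np.ndarray, labels: np.ndarray, config: MetaNetworkConfig
) -> MLPClassifier:
    """Train the fully-connected meta-network with cross-entropy loss.

    ``fused`` is the attention-fused feature matrix (one row per sample),
    ``labels`` integer class labels with every class present.
    """
    X = np.asarray(fused, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise MetaNetworkError("fused matrix and labels are misaligned")
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 1) or len(classes) < 1:
        raise MetaNetworkError("every class needs at least one sample")
    net = MLPClassifier(
        hidden_layer_sizes=config.hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=config.seed,
        n_iter_no_change=config.epochs,  # run the full epoch budget
        tol=0.0,
        alpha=1e-4,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        net.fit(X, y)
    return net


def predict_proba_full(net: MLPClassifier, fused: np.ndarray, k: int) -> np.ndarray:
    """Class probabilities over all k classes in index order.

    The network may have seen only a subset of labels; absent classes get
    probability zero so downstream matrices keep a fixed width.
    """
    raw = net.predict_proba(np.asarray(fused, dtype=float))
    out = np.zeros((raw.shape[0], k))
    for j, cls in enumerate(net.classes_):
        out[:, int(cls)] = raw[:, j]
    return out
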