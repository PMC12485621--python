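"""Base binary classifier families and their hyperparameter search spaces.

Three families are supported as one-vs-rest / one-vs-one experts:
L2-regularized logistic regression, random forest, and gradient-boosted
trees (XGBoost). All estimators are built single-threaded and seeded so
that fits are reproducible on any machine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier

ALGORITHMS = ("logistic_regression", "random_forest", "xgboost")


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class BinaryClassifierSpec:
    """One base-classifier configuration: family + hyperparameters + seed."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise SpecError(
                f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}"
            )

    def build(self):
        """Instantiate the sklearn/xgboost estimator for this spec."""
        hp = dict(self.hyperparameters)
        if self.algorithm == "logistic_regression":
            return LogisticRegression(
                C=float(hp.get("C", 1.0)),
                solver="lbfgs",
                max_iter=int(hp.get("max_iter", 2000)),
                random_state=self.seed,
            )
        if self.algorithm == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(hp.get("n_estimators", 200)),
                max_depth=(None if hp.get("max_depth") in (None, 0)
                           else int(hp["max_depth"])),
                min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
                max_features=hp.get("max_features", "sqrt"),
                random_state=self.seed,
                n_jobs=1,
            )
        return XGBClassifier(
            n_estimators=int(hp.get("n_estimators", 200)),
            max_depth=int(hp.get("max_depth", 4)),
            learning_rate=float(hp.get("learning_rate", 0.1)),
            subsample=float(hp.get("subsample", 1.0)),
            reg_lambda=float(hp.get("reg_lambda", 1.0)),
            random_state=self.seed,
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
        )


#: Continuous dimensions are (low, high, scale) with scale "linear" or
#: "log"; integer dimensions add "int". Searched by the tuner.
DEFAULT_SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "logistic_regression": {
        "C": (1e-3, 1e3, "log"),
    },
    "random_forest": {
        "n_estimators": (50, 400, "linear", "int"),
        "max_depth": (2, 20, "linear", "int"),
        "min_samples_leaf": (1, 8, "linear", "int"),
    },
    "xgboost": {
        "n_estimators": (50, 400, "linear", "int"),
        "max_depth": (2, 8, "linear", "int"),
        "learning_rate": (0.01, 0.5, "log"),
    },
}


def decode_point(space: dict[str, tuple], u: np.ndarray) -> dict:
    """Map a unit-cube point to hyperparameter values."""
    hp = {}
    for (name, dim), x in zip(space.items(), u):
        lo, hi, scale = dim[0], dim[1], dim[2]
        if scale == "log":
            val = float(np.exp(np.log(lo) + x * (np.log(hi) - np.log(lo))))
        else:
            val = float(lo + x * (hi - lo))
        if len(dim) > 3 and dim[3] == "int":
            val = int(round(val))
        hp[name] = val
    return hp
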