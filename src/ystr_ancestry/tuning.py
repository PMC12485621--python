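"""Sequential model-based (Bayesian) hyperparameter optimization.

A Gaussian-process surrogate (Matérn 5/2) is fit to the evaluated
(point, score) pairs on the unit cube; the next point maximizes expected
improvement over a random candidate pool. The first few evaluations are
space-filling random draws. Everything is driven by one seed, so a tuning
run is exactly reproducible.

The objective maximized is mean stratified k-fold cross-validated
balanced accuracy — appropriate for the imbalanced positive/negative
splits that one-vs-rest decomposition creates.
"""

from __future__ import annotations

import warnings
from typing import Callable

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from scipy.stats import norm

from .base import DEFAULT_SEARCH_SPACES, BinaryClassifierSpec, decode_point


class TuningError(ValueError):
    pass


def cv_balanced_accuracy(
    spec: BinaryClassifierSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int,
    seed: int,
) -> float:
    """Mean out-of-fold balanced accuracy under stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for tr, te in skf.split(X, y):
            est = spec.build()
            est.fit(X[tr], y[tr])
            scores.append(balanced_accuracy_score(y[te], est.predict(X[te])))
    return float(np.mean(scores))


def propose_points(
    objective: Callable[[np.ndarray], float],
    n_dims: int,
    budget: int,
    seed: int,
    n_initial: int | None = None,
    n_candidates: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Generic maximize-on-the-unit-cube SMBO loop.

    Returns (points, scores) for all ``budget`` evaluations. The surrogate
    is refit after every evaluation once the random warm-up is exhausted.
    """
    if budget < 1:
        raise TuningError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if n_initial is None:
        n_initial = min(budget, max(3, n_dims + 1))
    pts: list[np.ndarray] = []
    vals: list[float] = []
    for i in range(budget):
        if i < n_initial:
            u = rng.random(n_dims)
        else:
            X = np.vstack(pts)
            z = np.asarray(vals)
            gp = GaussianProcessRegressor(
                kernel=Matern(length_scale=np.full(n_dims, 0.3), nu=2.5),
                alpha=1e-6,
                normalize_y=True,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gp.fit(X, z)
                cand = rng.random((n_candidates, n_dims))
                mu, sd = gp.predict(cand, return_std=True)
            best = z.max()
            sd = np.maximum(sd, 1e-12)
            imp = mu - best
            ei = imp * norm.cdf(imp / sd) + sd * norm.pdf(imp / sd)
            u = cand[int(np.argmax(ei))]
        pts.append(u)
        vals.append(float(objective(u)))
    return np.vstack(pts), np.asarray(vals)


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str,
    *,
    space: dict[str, tuple] | None = None,
    n_folds: int = 3,
    budget: int = 16,
    seed: int = 0,
) -> BinaryClassifierSpec:
    """Tune one base-classifier family on a binary problem.

    Returns the spec with the best mean cross-validated balanced accuracy
    among the ``budget`` evaluated points. Deterministic given ``seed``.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TuningError("both classes must be present for tuning")
    if n_folds < 2:
        raise TuningError("n_folds must be >= 2")
    if space is None:
        space = DEFAULT_SEARCH_SPACES[algorithm]
    if not space:
        return BinaryClassifierSpec(algorithm=algorithm, hyperparameters={}, seed=seed)

    X = np.asarray(X, dtype=float)
    cache: dict[tuple, float] = {}

    def objective(u: np.ndarray) -> float:
        hp = decode_point(space, u)
        key = tuple(sorted(hp.items()))
        if key not in cache:
            spec = BinaryClassifierSpec(algorithm=algorithm, hyperparameters=hp, seed=seed)
            cache[key] = cv_balanced_accuracy(spec, X, y, n_folds, seed)
        return cache[key]

    pts, vals = propose_points(objective, n_dims=len(space), budget=budget, seed=seed)
    best_u = pts[int(np.argmax(vals))]
    return BinaryClassifierSpec(
        algorithm=algorithm, hyperparameters=decode_point(space, best_u), seed=seed
    )


def random_search(
    objective: Callable[[np.ndarray], float],
    n_dims: int,
    budget: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Same-budget uniform random search; the tuner's baseline comparator."""
    rng = np.random.default_rng(seed)
    pts = rng.random((budget, n_dims))
    vals = np.asarray([objective(u) for u in pts])
    return pts, vals
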