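"""Platt scaling: post-hoc sigmoid calibration of classifier scores.

A raw score s (probability or logit) is mapped to

    P(y = 1 | s) = 1 / (1 + exp(A·s + B))

with (A, B) fit by maximum likelihood. A well-oriented classifier
(higher score = more positive) yields A < 0. Targets are smoothed the
way Platt proposed — positives get (N+ + 1)/(N+ + 2), negatives
1/(N− + 2) — which keeps the likelihood bounded and the parameters
finite even on perfectly separable scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from sklearn.model_selection import StratifiedKFold


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class CalibrationParams:
    A: float
    B: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and np.isfinite(self.B)):
            raise CalibrationError("calibration parameters must be finite")


def platt_apply(params: CalibrationParams, s) -> np.ndarray | float:
    """Evaluate 1/(1+exp(A·s+B)); strictly monotone in s for A != 0."""
    z = params.A * np.asarray(s, dtype=float) + params.B
    out = expit(-z)
    return float(out) if out.ndim == 0 else out


def _nll(ab: np.ndarray, s: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Smoothed-target negative log-likelihood and its gradient."""
    A, B = ab
    z = A * s + B
    # log p = -logaddexp(0, z);  log(1-p) = z - logaddexp(0, z)
    lse = np.logaddexp(0.0, z)
    nll = float(np.sum(lse - (1.0 - t) * z))
    p = expit(-z)
    # dNLL/dz = t - p  =>  grad = [sum((t-p)*s), sum(t-p)]
    diff = t - p
    return nll, np.array([np.dot(diff, s), diff.sum()])


def platt_fit(scores, y, n_folds: int = 3) -> CalibrationParams:
    """Maximum-likelihood sigmoid fit of scores to binary labels.

    Both classes must be present and there must be at least ``n_folds``
    samples (the fold count is also used by :func:`platt_cv_diagnostic`).
    """
    s = np.asarray(scores, dtype=float)
    t_raw = np.asarray(y, dtype=float)
    if s.shape != t_raw.shape or s.ndim != 1:
        raise CalibrationError("scores and labels must be equal-length 1-D")
    n_pos = int(np.sum(t_raw == 1))
    n_neg = int(np.sum(t_raw == 0))
    if n_pos == 0 or n_neg == 0:
        raise CalibrationError("both classes must be present for calibration")
    if s.size < n_folds:
        raise CalibrationError(f"need at least n_folds={n_folds} samples")
    # Platt's smoothed targets
    t = np.where(t_raw == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    x0 = np.array([0.0, np.log((n_neg + 1.0) / (n_pos + 1.0))])
    res = minimize(_nll, x0, args=(s, t), jac=True, method="BFGS",
                   options={"maxiter": 200, "gtol": 1e-10})
    A, B = res.x
    return CalibrationParams(A=float(A), B=float(B))


def nll_of_probs(probs: np.ndarray, y: np.ndarray, eps: float = 1e-12) -> float:
    """Mean binary cross-entropy of probability predictions."""
    p = np.clip(np.asarray(probs, dtype=float), eps, 1 - eps)
    t = np.asarray(y, dtype=float)
    return float(-np.mean(t * np.log(p) + (1 - t) * np.log(1 - p)))


def platt_cv_diagnostic(scores, y, n_folds: int = 3, seed: int = 0) -> dict:
    """Out-of-fold NLL before vs after calibration.

    Fits the sigmoid on each training fold and scores the held-out fold;
    reports mean raw-score NLL, mean calibrated NLL, and the improvement
    (positive = calibration helped held-out likelihood).
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(y)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    raw_nll, cal_nll = [], []
    for tr, te in skf.split(s.reshape(-1, 1), t):
        params = platt_fit(s[tr], t[tr], n_folds=2)
        raw_nll.append(nll_of_probs(np.clip(s[te], 0.0, 1.0), t[te]))
        cal_nll.append(nll_of_probs(platt_apply(params, s[te]), t[te]))
    return {
        "raw_nll": float(np.mean(raw_nll)),
        "calibrated_nll": float(np.mean(cal_nll)),
        "improvement": float(np.mean(raw_nll) - np.mean(cal_nll)),
    }
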