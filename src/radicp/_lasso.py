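"""Shared L1-penalized logistic machinery.

All penalized fits in this package minimize

    (1/n) * sum_i log(1 + exp(-t_i (w . x_i + b))) + lambda * ||w||_1

on standardized features.  scikit-learn's liblinear solver minimizes
``C * sum_i loss_i + ||w||_1``, so ``C = 1 / (n * lambda)``.  The smallest
penalty that zeroes every coefficient in the intercept-only stationary
point is ``lambda_max = ||X^T (y - mean(y))||_inf / n``; grids are
log-spaced from lambda_max down a fixed number of decades.
"""

from __future__ import annotations

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import RepeatedStratifiedKFold


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise zero-mean unit-variance scaling; constant columns get scale 1."""
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    grad = X_std.T @ (y - y.mean()) / n
    return float(np.max(np.abs(grad)))


def lambda_grid(lmax: float, size: int = 50, decades: float = 3.0) -> np.ndarray:
    """Log-spaced penalties from lambda_max down ``decades`` decades (descending)."""
    if lmax <= 0:
        lmax = 1e-4  # degenerate (constant-feature) design; any grid works
    return np.geomspace(lmax, lmax * 10.0 ** (-decades), size)


def fit_l1(
    X_std: np.ndarray, y: np.ndarray, lam: float, seed: int = 0
) -> tuple[np.ndarray, float]:
    """L1-logistic fit at one penalty on standardized features."""
    n = len(y)
    model = LogisticRegression(
        l1_ratio=1,
        C=1.0 / (n * lam),
        solver="liblinear",
        tol=1e-6,
        max_iter=1000,
        random_state=seed,
    )
    model.fit(X_std, y)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def cv_folds(
    y: np.ndarray, folds: int, repeats: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified repeated CV fold index pairs, deterministic given seed."""
    splitter = RepeatedStratifiedKFold(
        n_splits=folds, n_repeats=repeats, random_state=seed
    )
    return list(splitter.split(np.zeros_like(y), y))
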