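"""Feature preselection: lasso-based and stability-based.

The invariance stage enumerates feature subsets, so its candidate pool
must stay small.  Two preselection routes constrain the search space:

* **lasso**: the nonzero support of an L1-penalized logistic fit at the
  penalty chosen by repeated stratified cross-validation (MCC-scored),
  truncated to the strongest ``max_features`` coefficients;
* **stability**: selection frequencies over many class-stratified
  subsample refits of the whole L1 path — a feature counts as selected in
  a subsample if it is nonzero anywhere on the penalty grid; features at
  or above a frequency threshold are retained.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import _lasso
from .datamodel import CohortMetadata, FeatureTable
from .metrics import mcc_from_labels

logger = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of one selection stage.

    ``selected`` is an ordered list of feature indices into
    ``feature_names``; ``diagnostics`` holds one score per feature in the
    table (absolute coefficient at the chosen penalty, or selection
    frequency), and ``parameters`` records what was run.
    """

    method: str
    selected: list[int]
    diagnostics: np.ndarray
    parameters: dict[str, Any]
    feature_names: list[str]

    def __post_init__(self) -> None:
        if len(self.selected) != len(set(self.selected)):
            raise ValueError("selected indices contain duplicates")
        if self.selected and not all(
            0 <= i < len(self.feature_names) for i in self.selected
        ):
            raise ValueError("selected index out of range")

    @property
    def selected_names(self) -> list[str]:
        return [self.feature_names[i] for i in self.selected]

    def to_dict(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "selected": list(map(int, self.selected)),
            "selected_names": self.selected_names,
            "diagnostics": [float(d) for d in self.diagnostics],
            "parameters": self.parameters,
        }


def all_features_selection(table: FeatureTable) -> SelectionResult:
    """The trivial 'selection' that keeps every feature (the all-features recipe)."""
    p = table.n_features
    return SelectionResult(
        method="all",
        selected=list(range(p)),
        diagnostics=np.ones(p),
        parameters={},
        feature_names=list(table.feature_names),
    )


def preselect_lasso(
    table: FeatureTable,
    metadata: CohortMetadata,
    max_features: int = 20,
    folds: int = 3,
    repeats: int = 10,
    grid_size: int = 50,
    seed: int = 0,
) -> SelectionResult:
    """Nonzero support of an L1-logistic fit at the CV-chosen penalty.

    The penalty grid is log-spaced over 3 decades below lambda_max; each
    penalty is scored by mean MCC over ``repeats x folds`` stratified CV
    (probability threshold 0.5), ties broken toward the larger penalty.
    The final support comes from a refit on all data at the chosen
    penalty, ranked by descending absolute coefficient and truncated to
    ``max_features``.
    """
    X, y = table.values, metadata.y
    params = {
        "max_features": max_features,
        "folds": folds,
        "repeats": repeats,
        "grid_size": grid_size,
        "seed": seed,
    }
    X_std, _, _ = _lasso.standardize(X)
    lmax = _lasso.lambda_max(X_std, y)
    if lmax == 0.0:
        logger.warning("all features constant or uninformative at path start; "
                       "empty lasso preselection")
        return SelectionResult("lasso", [], np.zeros(X.shape[1]), params, list(table.feature_names))
    grid = _lasso.lambda_grid(lmax, grid_size)
    folds_ix = _lasso.cv_folds(y, folds, repeats, seed)

    scores = np.zeros(len(grid))
    for tr, va in folds_ix:
        Xtr, mean, scale = _lasso.standardize(X[tr])
        Xva = (X[va] - mean) / scale
        for j, lam in enumerate(grid):
            coef, b0 = _lasso.fit_l1(Xtr, y[tr], lam, seed)
            pred = (Xva @ coef + b0 >= 0.0).astype(int)
            scores[j] += mcc_from_labels(y[va], pred)
    scores /= len(folds_ix)
    lam_star = grid[int(np.argmax(scores))]  # grid descends: argmax favors larger lambda

    coef, _ = _lasso.fit_l1(X_std, y, lam_star, seed)
    diagnostics = np.abs(coef)
    nonzero = np.flatnonzero(coef)
    order = nonzero[np.argsort(-diagnostics[nonzero], kind="stable")]
    selected = [int(i) for i in order[:max_features]]
    params["lambda_star"] = float(lam_star)
    return SelectionResult("lasso", selected, diagnostics, params, list(table.feature_names))


def stratified_subsample(
    rng: np.random.Generator, y: np.ndarray, fraction: float
) -> np.ndarray:
    """Class-stratified subsample indices: round(fraction * n_class) per class,
    at least one sample per class so extreme imbalance never drops a class."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * len(members))))
        idx.append(rng.choice(members, size=k, replace=False))
    out = np.concatenate(idx)
    out.sort()
    return out


def preselect_stability(
    table: FeatureTable,
    metadata: CohortMetadata,
    n_subsamples: int = 100,
    subsample_fraction: float = 0.5,
    penalty_grid: np.ndarray | None = None,
    frequency_threshold: float = 0.6,
    max_features: int = 20,
    seed: int = 0,
) -> SelectionResult:
    """Stability selection over class-stratified subsample refits.

    A feature's frequency is the fraction of subsamples in which it is
    nonzero anywhere on the penalty grid.  Features with frequency >=
    ``frequency_threshold`` are kept, ordered by descending frequency
    (index order breaks ties), truncated to ``max_features``.
    """
    if n_subsamples < 2:
        raise ValueError("n_subsamples must be >= 2")
    if not 0.0 < subsample_fraction < 1.0:
        raise ValueError("subsample_fraction must lie in (0, 1)")
    X, y = table.values, metadata.y
    if penalty_grid is None:
        X_std, _, _ = _lasso.standardize(X)
        penalty_grid = _lasso.lambda_grid(_lasso.lambda_max(X_std, y), 50)
    penalty_grid = np.asarray(penalty_grid, dtype=float)

    rng = np.random.default_rng(seed)
    hits = np.zeros(X.shape[1])
    for _ in range(n_subsamples):
        sub = stratified_subsample(rng, y, subsample_fraction)
        if len(np.unique(y[sub])) < 2:  # unreachable under stratification; guard anyway
            raise RuntimeError("subsample lost a class")
        Xs, _, _ = _lasso.standardize(X[sub])
        ever = np.zeros(X.shape[1], dtype=bool)
        for lam in penalty_grid:
            coef, _ = _lasso.fit_l1(Xs, y[sub], lam, seed)
            ever |= coef != 0.0
        hits += ever
    freq = hits / n_subsamples

    candidates = np.flatnonzero(freq >= max(frequency_threshold, np.finfo(float).tiny))
    order = candidates[np.lexsort((candidates, -freq[candidates]))]
    selected = [int(i) for i in order[:max_features]]
    params = {
        "n_subsamples": n_subsamples,
        "subsample_fraction": subsample_fraction,
        "frequency_threshold": frequency_threshold,
        "max_features": max_features,
        "seed": seed,
        "penalty_grid_size": int(len(penalty_grid)),
    }
    return SelectionResult("stability", selected, freq, params, list(table.feature_names))
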