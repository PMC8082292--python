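"""MCC-tuned L1-regularized logistic classification and the model recipes.

The final classifier is an L1-penalized logistic model whose penalty is
chosen by repeated stratified cross-validation (10 repeats x 3 folds by
default) maximizing the Matthews correlation coefficient at probability
threshold 0.5.  Three recipes are compared throughout the package:

* **A1** — lasso preselection, then invariance selection, then the tuned
  lasso-logistic model;
* **A2** — stability preselection, then invariance selection, then the
  tuned model;
* **B**  — the common radiomics baseline: the tuned lasso-logistic model
  on all features, no invariance filtering.

Features are standardized with training-split statistics before every
penalized fit, and the stored model carries those constants so prediction
applies the identical transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.special import expit

from . import _lasso
from .datamodel import CohortMetadata, FeatureTable
from .invariance import InvarianceResult, select_invariant
from .metrics import auc, confusion, mcc, mcc_from_labels, sens_spec_acc
from .preselect import (
    SelectionResult,
    all_features_selection,
    preselect_lasso,
    preselect_stability,
)

logger = logging.getLogger(__name__)


@dataclass
class TunedModel:
    """A fitted penalized logistic model with its tuning trace.

    Coefficients live on the standardized feature scale; ``feature_means``
    and ``feature_scales`` are the training statistics that reproduce it.
    ``cv_trace`` maps each penalty on the searched grid to the mean and
    standard deviation of the CV MCC; ``cv_metrics`` holds the per-fold
    metric values at the chosen penalty (the basis for CV percentile CIs).
    """

    feature_names: list[str]
    coefficients: np.ndarray
    intercept: float
    lambda_star: float
    lambda_grid: np.ndarray
    cv_trace: dict[str, np.ndarray]
    cv_metrics: dict[str, np.ndarray]
    feature_means: np.ndarray
    feature_scales: np.ndarray
    recipe: str = ""

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.feature_names):
            raise ValueError("coefficients do not align with feature names")
        if not np.any(np.isclose(self.lambda_grid, self.lambda_star)):
            raise ValueError("lambda_star must belong to the searched grid")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def coefficient_table(self) -> list[dict[str, Any]]:
        """Nonzero coefficients as rows, the data behind a coefficient chart."""
        rows = [
            {"feature": n, "coefficient": float(c)}
            for n, c in zip(self.feature_names, self.coefficients)
            if c != 0.0
        ]
        rows.sort(key=lambda r: -abs(r["coefficient"]))
        return rows

    def to_dict(self) -> dict[str, Any]:
        return {
            "recipe": self.recipe,
            "feature_names": self.feature_names,
            "coefficients": [float(c) for c in self.coefficients],
            "intercept": float(self.intercept),
            "lambda_star": float(self.lambda_star),
            "feature_means": [float(m) for m in self.feature_means],
            "feature_scales": [float(s) for s in self.feature_scales],
        }


def tune_lambda(
    table: FeatureTable,
    metadata: CohortMetadata,
    subset: Sequence[int] | None = None,
    grid_size: int = 50,
    repeats: int = 10,
    folds: int = 3,
    seed: int = 0,
    recipe: str = "",
) -> TunedModel:
    """Tune the L1 penalty by repeated stratified CV maximizing MCC.

    The grid is log-spaced over 3 decades below lambda_max.  Ties in mean
    CV MCC break toward the larger (sparser) penalty.  The returned model
    is refitted on all supplied data at the chosen penalty.
    """
    y = metadata.y
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"the smaller class has {counts.min()} samples, fewer than {folds} "
            "folds; use fewer folds"
        )
    idx = list(range(table.n_features)) if subset is None else [int(i) for i in subset]
    if not idx:
        raise ValueError("cannot tune a model on an empty feature subset")
    names = [table.feature_names[i] for i in idx]
    X = table.values[:, idx]

    X_all, mean_all, scale_all = _lasso.standardize(X)
    grid = _lasso.lambda_grid(_lasso.lambda_max(X_all, y), grid_size)
    fold_ix = _lasso.cv_folds(y, folds, repeats, seed)

    fold_mcc = np.zeros((len(fold_ix), len(grid)))
    for fi, (tr, va) in enumerate(fold_ix):
        Xtr, m, s = _lasso.standardize(X[tr])
        Xva = (X[va] - m) / s
        for j, lam in enumerate(grid):
            coef, b0 = _lasso.fit_l1(Xtr, y[tr], lam, seed)
            pred = (Xva @ coef + b0 >= 0.0).astype(int)
            fold_mcc[fi, j] = mcc_from_labels(y[va], pred)

    mean_mcc = fold_mcc.mean(axis=0)
    j_star = int(np.argmax(mean_mcc))  # grid descends; first max = largest lambda
    lam_star = float(grid[j_star])

    # per-fold metrics at the chosen penalty, for CV percentile intervals
    cv_metrics: dict[str, list[float]] = {k: [] for k in ("mcc", "auc", "acc", "sens", "spec")}
    for tr, va in fold_ix:
        Xtr, m, s = _lasso.standardize(X[tr])
        Xva = (X[va] - m) / s
        coef, b0 = _lasso.fit_l1(Xtr, y[tr], lam_star, seed)
        score = Xva @ coef + b0
        pred = (score >= 0.0).astype(int)
        cm = confusion(y[va], pred, 1)
        sens, spec, acc = sens_spec_acc(cm)
        cv_metrics["mcc"].append(mcc(cm))
        cv_metrics["acc"].append(acc)
        cv_metrics["sens"].append(sens)
        cv_metrics["spec"].append(spec)
        try:
            cv_metrics["auc"].append(auc(score, y[va]))
        except ValueError:
            cv_metrics["auc"].append(float("nan"))

    coef, b0 = _lasso.fit_l1(X_all, y, lam_star, seed)
    return TunedModel(
        feature_names=names,
        coefficients=coef,
        intercept=b0,
        lambda_star=lam_star,
        lambda_grid=grid,
        cv_trace={"lambda": grid, "mean_mcc": mean_mcc, "sd_mcc": fold_mcc.std(axis=0)},
        cv_metrics={k: np.asarray(v) for k, v in cv_metrics.items()},
        feature_means=mean_all,
        feature_scales=scale_all,
        recipe=recipe,
    )


def predict(model: TunedModel, table: FeatureTable) -> tuple[np.ndarray, np.ndarray]:
    """Positive-class probability and 0.5-threshold hard label per sample."""
    missing = [n for n in model.feature_names if n not in table.feature_names]
    if missing:
        raise ValueError(f"table is missing model features: {missing}")
    idx = [table.feature_names.index(n) for n in model.feature_names]
    X = (table.values[:, idx] - model.feature_means) / model.feature_scales
    eta = X @ model.coefficients + model.intercept
    prob = expit(eta)
    return prob, (prob >= 0.5).astype(int)


@dataclass
class Recipe:
    """One of the three model-building recipes (A1, A2, B)."""

    tag: str
    preselection: str  # "lasso", "stability", or "all"
    use_invariance: bool
    preselect_params: dict[str, Any] = field(default_factory=dict)
    alpha: float = 0.05
    max_subset_size: int = 4
    tune_params: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def a1(cls, **overrides: Any) -> "Recipe":
        return cls(tag="A1", preselection="lasso", use_invariance=True, **overrides)

    @classmethod
    def a2(cls, **overrides: Any) -> "Recipe":
        return cls(tag="A2", preselection="stability", use_invariance=True, **overrides)

    @classmethod
    def b(cls, **overrides: Any) -> "Recipe":
        return cls(tag="B", preselection="all", use_invariance=False, **overrides)


@dataclass
class RecipeFit:
    """Everything produced while fitting one recipe on one training set."""

    recipe: Recipe
    model: TunedModel
    preselection: SelectionResult
    invariance: InvarianceResult | None
    final_selection: SelectionResult


def fit_recipe(
    table: FeatureTable,
    metadata: CohortMetadata,
    recipe: Recipe,
    seed: int = 0,
) -> RecipeFit:
    """Run one recipe end to end on a training cohort.

    For the invariance recipes, an empty invariant set falls back to the
    preselection pool (with a prominent warning); the model is then tuned
    on whatever feature set survived.
    """
    if recipe.preselection == "lasso":
        pre = preselect_lasso(table, metadata, seed=seed, **recipe.preselect_params)
    elif recipe.preselection == "stability":
        pre = preselect_stability(table, metadata, seed=seed, **recipe.preselect_params)
    elif recipe.preselection == "all":
        pre = all_features_selection(table)
    else:
        raise ValueError(f"unknown preselection {recipe.preselection!r}")

    inv = None
    subset = pre.selected
    if recipe.use_invariance:
        inv = select_invariant(
            pre, table, metadata,
            alpha=recipe.alpha, max_subset_size=recipe.max_subset_size,
        )
        if inv.invariant_features:
            subset = inv.invariant_features
        else:
            logger.warning(
                "recipe %s: empty invariant set; FALLING BACK to the %d-feature "
                "preselection pool", recipe.tag, len(pre.selected),
            )
        final = inv.as_selection(list(table.feature_names))
        if not inv.invariant_features:
            final = pre
    else:
        final = pre

    model = tune_lambda(
        table, metadata, subset=subset, seed=seed, recipe=recipe.tag,
        **recipe.tune_params,
    )
    return RecipeFit(recipe=recipe, model=model, preselection=pre,
                     invariance=inv, final_selection=final)
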