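"""Evaluation scenarios, reports, and model comparison.

Two scenarios mirror how multicenter radiogenomics models are validated:

* **leave-one-center-out (LOCO)** — each center in turn is held out as an
  independent test set; preselection, invariance selection and penalty
  tuning all run on the remaining centers only (which also serve as the
  invariance environments);
* **stratified split** — a single outcome-stratified 70/30 partition of
  the pooled cohort, pipeline on the 70%, report on the 30%.

Each (test set, recipe) pair yields an :class:`EvaluationReport` with the
confusion matrix, AUC / accuracy / sensitivity / specificity / MCC with
95% CIs (stratified bootstrap for AUC and MCC, Wilson score intervals for
the proportions), the no-information-rate test, and CV summaries; each
scenario additionally carries pairwise AUC-comparison p-values (paired
stratified bootstrap) with Holm adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .classifier import Recipe, RecipeFit, fit_recipe, predict
from .datamodel import CohortMetadata, FeatureTable
from .metrics import (
    ConfusionMatrix,
    auc,
    bootstrap_auc_ci,
    compare_auc,
    confusion,
    holm_adjust,
    mcc,
    mcc_from_labels,
    nir_test,
    sens_spec_acc,
    truncate2,
    wilson_interval,
)
from .preselect import SelectionResult

__all__ = [
    "ConfusionMatrix", "confusion", "mcc", "mcc_from_labels", "sens_spec_acc",
    "wilson_interval", "truncate2", "auc", "bootstrap_auc_ci", "compare_auc",
    "holm_adjust", "nir_test", "EvaluationReport", "ScenarioResult",
    "evaluate_model", "run_loco", "run_split", "selection_frequency_table",
]

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Test-set performance of one recipe in one scenario run.

    ``metrics`` maps each metric name to ``{"point": x, "ci": (lo, hi)}``;
    an undefined metric (class absent from the test set) carries NaN and a
    ``None`` CI.  CV entries summarize the per-fold values at the chosen
    penalty as mean plus a percentile interval — a convention-dependent
    construction, flagged as such here.
    """

    scenario: str
    recipe: str
    confusion_matrix: ConfusionMatrix
    metrics: dict[str, dict[str, Any]]
    nir: float
    nir_pvalue: float
    cv_metrics: dict[str, dict[str, Any]]
    n_test: int
    seed: int
    lambda_star: float
    n_features_used: int
    fallback_used: bool = False

    def __post_init__(self) -> None:
        for name, m in self.metrics.items():
            ci = m.get("ci")
            if ci is not None and not np.isnan(m["point"]):
                if not (ci[0] - 1e-12 <= m["point"] <= ci[1] + 1e-12):
                    raise ValueError(f"{name}: point estimate outside its CI")
        if not 0.0 <= self.nir_pvalue <= 1.0:
            raise ValueError("NIR p-value outside [0, 1]")

    def to_dict(self) -> dict[str, Any]:
        def fmt(m: Mapping[str, Any]) -> dict[str, Any]:
            out: dict[str, Any] = {"point": m["point"]}
            if m.get("ci") is not None:
                lo, hi = m["ci"]
                out["ci"] = [lo, hi]
                out["ci_display"] = [truncate2(lo), truncate2(hi)]
            else:
                out["ci"] = None
            return out

        return {
            "scenario": self.scenario,
            "recipe": self.recipe,
            "confusion_matrix": self.confusion_matrix.to_dict(),
            "metrics": {k: fmt(v) for k, v in self.metrics.items()},
            "nir": self.nir,
            "nir_pvalue": self.nir_pvalue,
            "cv_metrics": {k: dict(v) for k, v in self.cv_metrics.items()},
            "n_test": self.n_test,
            "seed": self.seed,
            "lambda_star": self.lambda_star,
            "n_features_used": self.n_features_used,
            "fallback_used": self.fallback_used,
        }


@dataclass
class ScenarioResult:
    """All reports and model comparisons from one scenario run."""

    scenario: str
    reports: dict[str, dict[str, EvaluationReport]]  # unit -> recipe tag -> report
    fits: dict[str, dict[str, RecipeFit]]
    comparisons: list[dict[str, Any]]

    def all_reports(self) -> list[EvaluationReport]:
        return [r for unit in self.reports.values() for r in unit.values()]


def evaluate_model(
    fit: RecipeFit,
    table: FeatureTable,
    metadata: CohortMetadata,
    scenario: str,
    n_boot: int = 2000,
    seed: int = 0,
) -> EvaluationReport:
    """Score a fitted recipe on a test cohort and assemble the full report."""
    if len(metadata.sample_ids) == 0:
        raise ValueError("empty test set")
    y = metadata.y
    prob, pred = predict(fit.model, table)
    cm = confusion(y, pred, 1)
    sens, spec, acc = sens_spec_acc(cm)

    metrics: dict[str, dict[str, Any]] = {}
    both_classes = cm.tp + cm.fn > 0 and cm.tn + cm.fp > 0
    if both_classes:
        point_auc = auc(prob, y)
        metrics["auc"] = {"point": point_auc,
                         "ci": bootstrap_auc_ci(prob, y, n_boot=n_boot, seed=seed)}
        metrics["mcc"] = {"point": mcc(cm),
                         "ci": _bootstrap_mcc_ci(y, pred, n_boot=n_boot, seed=seed)}
    else:
        logger.warning("%s: a class is absent from the test set; AUC and MCC "
                       "CIs are flagged undefined", scenario)
        metrics["auc"] = {"point": float("nan"), "ci": None}
        metrics["mcc"] = {"point": mcc(cm), "ci": None}
    metrics["acc"] = {"point": acc, "ci": wilson_interval(cm.tp + cm.tn, cm.total)}
    metrics["sens"] = (
        {"point": sens, "ci": wilson_interval(cm.tp, cm.tp + cm.fn)}
        if cm.tp + cm.fn else {"point": float("nan"), "ci": None}
    )
    metrics["spec"] = (
        {"point": spec, "ci": wilson_interval(cm.tn, cm.tn + cm.fp)}
        if cm.tn + cm.fp else {"point": float("nan"), "ci": None}
    )

    nir, nir_p = nir_test(cm)
    cv_summary = {
        name: {
            "mean": float(np.nanmean(vals)),
            "ci": [float(v) for v in np.nanquantile(vals, [0.025, 0.975])],
        }
        for name, vals in fit.model.cv_metrics.items()
    }
    return EvaluationReport(
        scenario=scenario,
        recipe=fit.recipe.tag,
        confusion_matrix=cm,
        metrics=metrics,
        nir=nir,
        nir_pvalue=nir_p,
        cv_metrics=cv_summary,
        n_test=len(y),
        seed=seed,
        lambda_star=fit.model.lambda_star,
        n_features_used=len(fit.model.feature_names),
        fallback_used=bool(fit.invariance and fit.invariance.fallback_used),
    )


def _bootstrap_mcc_ci(
    y: np.ndarray, pred: np.ndarray, n_boot: int, seed: int,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Class-stratified percentile bootstrap CI for the MCC of fixed predictions."""
    rng = np.random.default_rng(seed)
    ipos, ineg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate([
            rng.choice(ipos, size=len(ipos), replace=True),
            rng.choice(ineg, size=len(ineg), replace=True),
        ])
        reps[b] = mcc_from_labels(y[idx], pred[idx])
    alpha = 1.0 - confidence
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def _compare_recipes(
    fits: Mapping[str, RecipeFit],
    table: FeatureTable,
    metadata: CohortMetadata,
    unit: str,
    n_boot: int,
    seed: int,
) -> list[dict[str, Any]]:
    """Pairwise test-AUC comparisons between recipes on one test set."""
    y = metadata.y
    if len(np.unique(y)) < 2:
        return []
    scores = {tag: predict(f.model, table)[0] for tag, f in fits.items()}
    pairs = list(itertools.combinations(sorted(scores), 2))
    raws = [
        compare_auc(scores[a], scores[b], y, n_boot=n_boot, seed=seed)
        for a, b in pairs
    ]
    adj = holm_adjust(raws)
    return [
        {"unit": unit, "pair": [a, b], "p_raw": pr, "p_holm": ph}
        for (a, b), pr, ph in zip(pairs, raws, adj)
    ]


def default_recipes() -> list[Recipe]:
    return [Recipe.a1(), Recipe.a2(), Recipe.b()]


def run_loco(
    table: FeatureTable,
    metadata: CohortMetadata,
    recipes: Sequence[Recipe] | None = None,
    seed: int = 0,
    n_boot: int = 2000,
) -> ScenarioResult:
    """Leave-one-center-out evaluation.

    For each environment, the remaining environments form the training
    cohort (and the invariance environments); every recipe is fitted there
    and evaluated on the held-out environment.  The held-out test sets
    partition the cohort.
    """
    recipes = list(recipes) if recipes is not None else default_recipes()
    envs = metadata.environments
    if len(envs) < 2:
        raise ValueError("leave-one-center-out needs at least 2 environments")
    env = metadata.env_array

    reports: dict[str, dict[str, EvaluationReport]] = {}
    fits: dict[str, dict[str, RecipeFit]] = {}
    comparisons: list[dict[str, Any]] = []
    for e in envs:
        held = env == e
        tr_table, tr_meta = table.subset_samples(~held), metadata.subset(~held)
        te_table, te_meta = table.subset_samples(held), metadata.subset(held)
        scenario = f"loco:{e}"
        unit_fits: dict[str, RecipeFit] = {}
        unit_reports: dict[str, EvaluationReport] = {}
        for recipe in recipes:
            fit = fit_recipe(tr_table, tr_meta, recipe, seed=seed)
            unit_fits[recipe.tag] = fit
            unit_reports[recipe.tag] = evaluate_model(
                fit, te_table, te_meta, scenario, n_boot=n_boot, seed=seed
            )
        reports[e] = unit_reports
        fits[e] = unit_fits
        comparisons.extend(
            _compare_recipes(unit_fits, te_table, te_meta, e, n_boot, seed)
        )
    return ScenarioResult("loco", reports, fits, comparisons)


def run_split(
    table: FeatureTable,
    metadata: CohortMetadata,
    recipes: Sequence[Recipe] | None = None,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_boot: int = 2000,
) -> ScenarioResult:
    """Outcome-stratified split evaluation (70/30 by default).

    The test-set size is ``ceil((1 - train_fraction) * n)`` with per-class
    rounding handled by scikit-learn's stratified shuffle split, so n = 77
    at 70/30 gives a 53/24 partition.  Environments of the training
    samples still drive the invariance stage.
    """
    recipes = list(recipes) if recipes is not None else default_recipes()
    y = metadata.y
    splitter = StratifiedShuffleSplit(
        n_splits=1, train_size=train_fraction, random_state=seed
    )
    tr_idx, te_idx = next(splitter.split(np.zeros_like(y), y))
    mask_tr = np.zeros(len(y), dtype=bool)
    mask_tr[tr_idx] = True
    if min(np.bincount(y[tr_idx], minlength=2).min(),
           np.bincount(y[te_idx], minlength=2).min()) < 2:
        raise ValueError("stratified split left a part with fewer than 2 "
                         "samples of one class")

    tr_table, tr_meta = table.subset_samples(mask_tr), metadata.subset(mask_tr)
    te_table, te_meta = table.subset_samples(~mask_tr), metadata.subset(~mask_tr)

    unit_fits: dict[str, RecipeFit] = {}
    unit_reports: dict[str, EvaluationReport] = {}
    for recipe in recipes:
        fit = fit_recipe(tr_table, tr_meta, recipe, seed=seed)
        unit_fits[recipe.tag] = fit
        unit_reports[recipe.tag] = evaluate_model(
            fit, te_table, te_meta, "split", n_boot=n_boot, seed=seed
        )
    comparisons = _compare_recipes(unit_fits, te_table, te_meta, "split", n_boot, seed)
    return ScenarioResult("split", {"split": unit_reports}, {"split": unit_fits}, comparisons)


def selection_frequency_table(
    results: Sequence[SelectionResult],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """0/1 incidence of each feature across selection runs, with row totals.

    Rows are features selected at least once, sorted by descending total
    (feature name breaks ties); columns are the runs plus ``Total``.
    """
    if labels is None:
        labels = [f"run{i}" for i in range(len(results))]
    if len(labels) != len(results):
        raise ValueError("labels length must match results length")
    if not results:
        return pd.DataFrame(columns=["Total"])
    namespace = results[0].feature_names
    for r in results:
        if r.feature_names != namespace:
            raise ValueError("selection results do not share a feature namespace")
    incidence = pd.DataFrame(
        0, index=pd.Index(namespace, name="feature"), columns=list(labels)
    )
    for label, r in zip(labels, results):
        for i in r.selected:
            incidence.loc[namespace[i], label] = 1
    incidence["Total"] = incidence.sum(axis=1)
    incidence = incidence[incidence["Total"] > 0]
    order = incidence.reset_index().sort_values(
        ["Total", "feature"], ascending=[False, True]
    )["feature"]
    return incidence.loc[order]
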