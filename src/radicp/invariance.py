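"""Invariance-based feature selection across acquisition environments.

A feature subset S is *plausibly causal* if the conditional relationship
outcome | S looks the same in every environment.  The test used here, for
a binary outcome, follows the held-out-residual construction of invariant
causal prediction: for each environment e, a logistic model of the outcome
on S is fitted on all samples NOT in e, Pearson residuals
``r = (y - p) / sqrt(p (1 - p))`` are computed on e and on its complement,
and the two samples are compared with Welch two-sample tests on the means
of ``r`` and of each score component ``r * x_j`` (j in S).  Under the true
model every one of these quantities has conditional mean zero at any
covariate value, so all |S| + 1 mean comparisons are centered under the
null in every environment; the residual mean catches rate misfit and the
score means catch slope misfit.  Within an environment the tests are
Bonferroni-combined, and the per-environment p-values again:

    p_e = min(1, (|S| + 1) * min_k p_{e,k}),   p(S) = min(1, |E| * min_e p_e)

Pearson residuals are the residual type that keeps this construction
calibrated in a multicenter design: under the true model they have mean 0
and variance 1 conditional on *any* covariate value, so environments may
shift the feature distributions (different scanners, different
prevalences) without moving the residual means.  Deviance residuals lack
this property — their conditional mean varies with the fitted probability
— and a variance-comparison component (an F-type or Brown-Forsythe test)
is likewise confounded by covariate shift for a binary outcome, because
the residuals' conditional *distribution shape* depends on p(x) even when
their variance does not.  Both alternatives reject the true invariant set
with probability approaching 1 as per-center samples grow, so this module
deliberately tests conditional-mean-zero moments only.

Subsets with p(S) > alpha are *accepted*; the selected invariant features
are the intersection of all accepted subsets — a set that, with
probability at least 1 - alpha, contains only features from the true
invariant (causal) set.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .datamodel import CohortMetadata, FeatureTable
from .preselect import SelectionResult

logger = logging.getLogger(__name__)

#: inverse L2 strength of the ridge-stabilized logistic fits; large C means
#: a near-maximum-likelihood fit that stays finite under perfect separation
_RIDGE_C = 1e4
_PROB_EPS = 1e-10


@dataclass
class InvarianceResult:
    """Full ledger of one invariance-selection run."""

    candidate_pool: list[int]
    tested_sets: list[tuple[tuple[int, ...], float, bool]]
    invariant_features: list[int]
    alpha: float
    fallback_used: bool

    def __post_init__(self) -> None:
        for subset, p, accepted in self.tested_sets:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p-value {p} outside [0, 1] for subset {subset}")
            if accepted and not set(self.invariant_features) <= set(subset):
                raise ValueError(
                    "invariant features must be a subset of every accepted set"
                )

    @property
    def accepted_sets(self) -> list[tuple[int, ...]]:
        return [s for s, _, acc in self.tested_sets if acc]

    def as_selection(self, feature_names: list[str]) -> SelectionResult:
        diagnostics = np.zeros(len(feature_names))
        diagnostics[list(self.invariant_features)] = 1.0
        return SelectionResult(
            method="invariance",
            selected=list(self.invariant_features),
            diagnostics=diagnostics,
            parameters={
                "alpha": self.alpha,
                "fallback_used": self.fallback_used,
                "n_tested": len(self.tested_sets),
                "n_accepted": len(self.accepted_sets),
            },
            feature_names=feature_names,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "candidate_pool": list(map(int, self.candidate_pool)),
            "tested_sets": [
                {"subset": list(map(int, s)), "p_value": float(p), "accepted": bool(a)}
                for s, p, a in self.tested_sets
            ],
            "invariant_features": list(map(int, self.invariant_features)),
            "alpha": self.alpha,
            "fallback_used": self.fallback_used,
        }


def _pearson_residuals(y: np.ndarray, prob: np.ndarray) -> np.ndarray:
    prob = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
    return (y - prob) / np.sqrt(prob * (1.0 - prob))


def invariance_pvalue(
    subset: Sequence[int],
    table: FeatureTable,
    metadata: CohortMetadata,
) -> float:
    """Invariance p-value for one feature subset (may be empty).

    For each environment, a ridge-stabilized logistic model (tiny L2, so
    perfect separation stays finite) is fitted on the complement; the
    Pearson residual and its score components on the held-out environment
    are compared with those on the complement by Welch mean tests,
    Bonferroni-combined within and across environments.  A subset whose
    complement fit is infeasible in any environment (a single-class
    complement) is rejected with p = 0.
    """
    envs = metadata.environments
    if len(envs) < 2:
        raise ValueError("invariance analysis needs at least 2 environments")
    y = metadata.y
    env = metadata.env_array
    subset = list(subset)
    X = table.values[:, subset] if subset else np.empty((table.n_samples, 0))

    p_env = []
    for e in envs:
        held = env == e
        comp = ~held
        y_c, y_e = y[comp], y[held]
        if len(np.unique(y_c)) < 2:
            logger.info("subset %s: single-class complement for environment %r; "
                        "rejected with p = 0", subset, e)
            return 0.0
        if subset:
            model = LogisticRegression(
                l1_ratio=0, C=_RIDGE_C, solver="lbfgs", max_iter=2000
            )
            try:
                model.fit(X[comp], y_c)
            except Exception:  # pragma: no cover - lbfgs rarely hard-fails
                logger.info("subset %s: fit failed for environment %r; p = 0", subset, e)
                return 0.0
            prob_c = model.predict_proba(X[comp])[:, 1]
            prob_e = model.predict_proba(X[held])[:, 1]
        else:
            base = y_c.mean()
            prob_c = np.full(len(y_c), base)
            prob_e = np.full(len(y_e), base)
        r_c = _pearson_residuals(y_c, prob_c)
        r_e = _pearson_residuals(y_e, prob_e)

        # moments with conditional mean zero under the true model: the
        # residual itself and one score component per subset feature
        M_c = np.column_stack([r_c] + [r_c * X[comp, j] for j in range(len(subset))])
        M_e = np.column_stack([r_e] + [r_e * X[held, j] for j in range(len(subset))])
        if len(r_e) >= 2:
            p_cols = []
            with warnings.catch_warnings():
                # near-constant residual columns trigger a scipy precision
                # warning; the resulting NaN p-value is handled below
                warnings.simplefilter("ignore", RuntimeWarning)
                for k in range(M_c.shape[1]):
                    p_k = stats.ttest_ind(M_e[:, k], M_c[:, k], equal_var=False).pvalue
                    p_cols.append(1.0 if math.isnan(p_k) else float(p_k))
            p_env.append(min(1.0, len(p_cols) * min(p_cols)))
        else:
            p_env.append(1.0)  # a single held-out sample carries no mean evidence

    return float(min(1.0, len(envs) * min(p_env)))


def select_invariant(
    pool: SelectionResult | Sequence[int],
    table: FeatureTable,
    metadata: CohortMetadata,
    alpha: float = 0.05,
    max_subset_size: int = 4,
    enumeration_cap: int = 50_000,
) -> InvarianceResult:
    """Enumerate subsets of the candidate pool and intersect the accepted ones.

    All subsets of the pool up to ``max_subset_size`` (including the empty
    set) are tested; those with p > alpha are accepted, and the invariant
    features are the intersection of the accepted subsets.  If no subset
    is accepted the result is empty with ``fallback_used=True`` —
    downstream model recipes then fall back to the preselection pool with
    a prominent warning.
    """
    indices = list(pool.selected) if isinstance(pool, SelectionResult) else [int(i) for i in pool]
    m = len(indices)
    n_subsets = sum(math.comb(m, k) for k in range(0, min(m, max_subset_size) + 1))
    if n_subsets > enumeration_cap:
        raise ValueError(
            f"enumeration of {n_subsets} subsets exceeds the cap of {enumeration_cap}; "
            "shrink the preselection pool or max_subset_size"
        )

    tested: list[tuple[tuple[int, ...], float, bool]] = []
    accepted: list[set[int]] = []
    for k in range(0, min(m, max_subset_size) + 1):
        for combo in itertools.combinations(indices, k):
            p = invariance_pvalue(combo, table, metadata)
            acc = p > alpha
            tested.append((combo, p, acc))
            if acc:
                accepted.append(set(combo))

    if accepted:
        invariant = set(indices)
        for s in accepted:
            invariant &= s
    else:
        invariant = set()
    # an empty intersection (no acceptances, or acceptances that intersect to
    # nothing, e.g. the empty set accepted) flags the downstream fallback
    fallback = not invariant
    if fallback:
        logger.warning(
            "invariance selection at alpha=%.3g produced an empty intersection "
            "(%d of %d subsets accepted); fallback flagged",
            alpha, len(accepted), len(tested),
        )
    return InvarianceResult(
        candidate_pool=indices,
        tested_sets=tested,
        invariant_features=sorted(invariant),
        alpha=alpha,
        fallback_used=fallback,
    )
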