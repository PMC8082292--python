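"""Binary-classification metrics, confidence intervals, and tests.

Conventions used throughout:

* confusion matrices are oriented rows = prediction, columns = reference;
* the positive class is configurable and defaults to IDH wild-type
  elsewhere in the package; metrics here only see the 0/1 encoding;
* MCC of a degenerate matrix (any marginal zero) is defined as 0;
* reported interval endpoints may be truncated (not rounded) to two
  decimals for display; full precision is always retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts, rows = prediction, columns = reference.

    ``tp`` counts samples predicted positive that are positive in the
    reference, and so on.  ``positive_class`` records which original label
    plays the positive role.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: str = "positive"

    def __post_init__(self) -> None:
        for v in (self.tp, self.fp, self.fn, self.tn):
            if v < 0 or int(v) != v:
                raise ValueError("confusion-matrix counts must be non-negative integers")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """[[pred-pos & ref-pos, pred-pos & ref-neg], [pred-neg & ref-pos, pred-neg & ref-neg]]"""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "positive_class": self.positive_class,
        }


def confusion(
    labels_true: Sequence, labels_pred: Sequence, positive_class
) -> ConfusionMatrix:
    """Build the prediction-by-reference confusion matrix."""
    yt = np.asarray(labels_true)
    yp = np.asarray(labels_pred)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("labels_true and labels_pred must be 1-D and equal length")
    if len(yt) == 0:
        raise ValueError("empty label vectors")
    t = yt == positive_class if yt.dtype == object or yt.dtype.kind in "US" else yt == positive_class
    p = yp == positive_class if yp.dtype == object or yp.dtype.kind in "US" else yp == positive_class
    return ConfusionMatrix(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
        positive_class=str(positive_class),
    )


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def mcc_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """MCC on 0/1-encoded labels (1 = positive)."""
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    return mcc(ConfusionMatrix(
        tp=int(np.sum((yp == 1) & (yt == 1))),
        fp=int(np.sum((yp == 1) & (yt == 0))),
        fn=int(np.sum((yp == 0) & (yt == 1))),
        tn=int(np.sum((yp == 0) & (yt == 0))),
    ))


def sens_spec_acc(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); NaN flags an empty denominator."""
    sens = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else float("nan")
    spec = cm.tn / (cm.tn + cm.fp) if cm.tn + cm.fp else float("nan")
    acc = (cm.tp + cm.tn) / cm.total if cm.total else float("nan")
    return sens, spec, acc


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - confidence, method="wilson")
    return float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0))


def truncate2(x: float) -> float:
    """Truncate (toward zero) to 2 decimals — the display convention for
    interval endpoints; e.g. 0.9487 -> 0.94."""
    return math.trunc(x * 100) / 100


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (pairwise-comparison estimator, midranks for ties)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _auc_rows(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise AUC for matrices of resampled positive/negative scores."""
    gt = (pos[:, :, None] > neg[:, None, :]).mean(axis=(1, 2))
    eq = (pos[:, :, None] == neg[:, None, :]).mean(axis=(1, 2))
    return gt + 0.5 * eq


def bootstrap_auc_ci(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
    confidence: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC with class-stratified resampling.

    Each replicate resamples the positive and negative score sets
    separately (so both classes are always present) and recomputes the
    rank AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("bootstrap AUC CI requires both classes present")
    rng = np.random.default_rng(seed)
    bpos = rng.choice(pos, size=(n_boot, len(pos)), replace=True)
    bneg = rng.choice(neg, size=(n_boot, len(neg)), replace=True)
    reps = _auc_rows(bpos, bneg)
    alpha = 1.0 - confidence
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def compare_auc(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> float:
    """Two-sided p-value for AUC_a != AUC_b via paired stratified bootstrap.

    The same resampled sample indices are applied to both score vectors,
    stratified by class; p = 2 * min(frac(dAUC <= 0), frac(dAUC >= 0)),
    floored at 1/n_boot and capped at 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels).astype(int)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise ValueError("scores_a, scores_b and labels must have equal length")
    ipos, ineg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    if len(ipos) == 0 or len(ineg) == 0:
        raise ValueError("AUC comparison requires both classes present")
    rng = np.random.default_rng(seed)
    rpos = rng.choice(ipos, size=(n_boot, len(ipos)), replace=True)
    rneg = rng.choice(ineg, size=(n_boot, len(ineg)), replace=True)
    delta = _auc_rows(sa[rpos], sa[rneg]) - _auc_rows(sb[rpos], sb[rneg])
    p = 2.0 * min(np.mean(delta <= 0), np.mean(delta >= 0))
    return float(min(1.0, max(p, 1.0 / n_boot)))


def holm_adjust(pvalues: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, monotone and capped at 1."""
    pv = np.asarray(pvalues, dtype=float)
    if len(pv) == 0:
        return []
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return [float(p) for p in multipletests(pv, method="holm")[1]]


def nir_test(cm: ConfusionMatrix) -> tuple[float, float]:
    """No-information rate and one-sided exact binomial p for accuracy > NIR.

    NIR is the majority-class fraction of the reference labels; the
    p-value is P(X >= correct) for X ~ Binomial(n, NIR).
    """
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    ref_pos = cm.tp + cm.fn
    nir = max(ref_pos, n - ref_pos) / n
    correct = cm.tp + cm.tn
    p = stats.binomtest(correct, n, nir, alternative="greater").pvalue
    return float(nir), float(p)
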