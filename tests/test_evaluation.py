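import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

from radicp.classifier import Recipe
from radicp.datamodel import write_report, read_report
from radicp.evaluation import (
    ConfusionMatrix,
    auc,
    bootstrap_auc_ci,
    compare_auc,
    confusion,
    holm_adjust,
    mcc,
    nir_test,
    run_loco,
    run_split,
    selection_frequency_table,
    sens_spec_acc,
    truncate2,
    wilson_interval,
)
from radicp.preselect import SelectionResult
from radicp.simulate import SyntheticConfig, simulate_multicenter

FAST_RECIPES = [
    Recipe.a1(
        preselect_params={"grid_size": 10, "repeats": 1, "max_features": 6},
        max_subset_size=2,
        tune_params={"grid_size": 10, "repeats": 1},
    ),
    Recipe.b(tune_params={"grid_size": 10, "repeats": 1}),
]


def labels_from_counts(tp, fp, fn, tn):
    """Reconstruct (reference, prediction) label vectors from 2x2 counts."""
    ref = ["wt"] * tp + ["mut"] * fp + ["wt"] * fn + ["mut"] * tn
    pred = ["wt"] * (tp + fp) + ["mut"] * (fn + tn)
    return ref, pred


class TestConfusion:
    def test_counts_from_reconstructed_labels(self):
        # held-out confusion matrix of the stability+invariance model in the
        # stratified-split scenario: rows prediction (mutant 13/1, WT 2/6)
        ref, pred = labels_from_counts(6, 2, 1, 13)
        cm = confusion(ref, pred, "wt")
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (6, 2, 1, 13)
        assert cm.total == 22

    def test_all_correct_toy(self):
        cm = confusion(["a", "b", "a"], ["a", "b", "a"], "a")
        assert cm.fp == 0 and cm.fn == 0
        assert cm.tp == 2 and cm.tn == 1

    def test_swapping_positive_class_transposes_roles(self):
        ref, pred = labels_from_counts(6, 2, 1, 13)
        cm_wt = confusion(ref, pred, "wt")
        cm_mut = confusion(ref, pred, "mut")
        assert (cm_mut.tp, cm_mut.fp, cm_mut.fn, cm_mut.tn) == (
            cm_wt.tn, cm_wt.fn, cm_wt.fp, cm_wt.tp
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            confusion([], [], 1)


class TestPointMetrics:
    def test_mcc_values(self):
        assert mcc(ConfusionMatrix(6, 2, 1, 13)) == pytest.approx(0.70, abs=0.005)
        assert mcc(ConfusionMatrix(0, 1, 15, 6)) == pytest.approx(-0.32, abs=0.005)
        assert mcc(ConfusionMatrix(5, 0, 0, 5)) == 1.0
        assert mcc(ConfusionMatrix(0, 0, 0, 5)) == 0.0  # degenerate -> 0

    def test_mcc_against_independent_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            tp, fp, fn, tn = rng.integers(0, 20, 4)
            if (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn) == 0:
                continue
            num = tp * tn - fp * fn
            den = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
            assert mcc(ConfusionMatrix(int(tp), int(fp), int(fn), int(tn))) == \
                pytest.approx(num / den)

    def test_sens_spec_acc_fractions(self):
        sens, spec, acc = sens_spec_acc(ConfusionMatrix(6, 2, 1, 13))
        assert (sens, spec, acc) == (6 / 7, 13 / 15, 19 / 22)

    def test_undefined_sensitivity_flagged(self):
        sens, spec, acc = sens_spec_acc(ConfusionMatrix(0, 3, 0, 7))
        assert np.isnan(sens) and spec == 7 / 10


class TestWilson:
    def test_reference_values(self):
        lo, hi = wilson_interval(13, 15)
        assert (truncate2(lo), truncate2(hi)) == (0.62, 0.96)
        lo, hi = wilson_interval(9, 11)
        # truncation (not rounding) reproduces the conventional display 0.94
        assert (truncate2(lo), truncate2(hi)) == (0.52, 0.94)

    def test_boundary_one_of_one(self):
        lo, hi = wilson_interval(1, 1)
        assert 0.0 <= lo <= 1.0 and hi == 1.0

    def test_contains_point_and_shrinks_with_n(self):
        for successes, n in [(3, 7), (15, 22), (60, 88)]:
            lo, hi = wilson_interval(successes, n)
            assert lo <= successes / n <= hi
        w1 = np.diff(wilson_interval(13, 15))
        w2 = np.diff(wilson_interval(130, 150))
        assert w2 < w1


class TestAUC:
    def test_perfect_ordering(self):
        assert auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_matches_bruteforce_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        for n in range(4, 31, 5):
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = rng.choice(np.linspace(0, 1, 7), size=n)  # ties likely
            pos, neg = s[y == 1], s[y == 0]
            brute = np.mean([
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a, b in itertools.product(pos, neg)
            ])
            assert auc(s, y) == pytest.approx(brute)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=200)
        y = rng.integers(0, 2, 200)
        assert auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_null_distribution_centered_at_half(self):
        vals = []
        for s in range(100):
            rng = np.random.default_rng(s)
            vals.append(auc(rng.normal(size=500), rng.integers(0, 2, 500)))
        # null sd at n=500 is ~0.026, so the +-0.06 band holds for ~98% of
        # draws; demand it for the bulk and the mean near one half
        assert np.mean([0.44 <= v <= 0.56 for v in vals]) >= 0.95
        assert 0.48 <= np.mean(vals) <= 0.52

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([0.1, 0.2], [1, 1])


class TestBootstrapAUC:
    def test_interval_contains_point(self):
        for s in range(10):
            rng = np.random.default_rng(s)
            y = np.array([0] * 30 + [1] * 30)
            scores = rng.normal(size=60) + y
            lo, hi = bootstrap_auc_ci(scores, y, n_boot=300, seed=s)
            assert lo <= auc(scores, y) <= hi

    def test_fixed_seed_identical(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 25 + [1] * 25)
        scores = rng.normal(size=50) + 0.8 * y
        assert bootstrap_auc_ci(scores, y, seed=9) == bootstrap_auc_ci(scores, y, seed=9)


class TestCompareAUC:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 20 + [1] * 20)
        s = rng.normal(size=40) + y
        assert compare_auc(s, s, y, n_boot=200, seed=0) == 1.0

    def test_antisymmetric(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 20 + [1] * 20)
        a = rng.normal(size=40) + y
        b = rng.normal(size=40)
        assert compare_auc(a, b, y, seed=3, n_boot=300) == \
            compare_auc(b, a, y, seed=3, n_boot=300)

    def test_power_against_random_scores(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            y = np.array([0] * 100 + [1] * 100)
            perfect = y + rng.random(200) * 0.5  # AUC 1.0
            noise = rng.normal(size=200)
            hits += compare_auc(perfect, noise, y, n_boot=400, seed=s) < 0.05
        assert hits >= 19


class TestHolmAndNIR:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.02]) == [0.02]

    def test_hand_computed_stepdown(self):
        # sorted: 0.01*3=0.03, 0.03*2=0.06, 0.04*1=0.04 -> monotone: 0.06
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(0)
        pv = rng.random(8)
        assert np.all(np.asarray(holm_adjust(pv)) >= pv)

    def test_reference_nir_case(self):
        # 22 test cases, 19 correct, majority class 15/22
        nir, p = nir_test(ConfusionMatrix(6, 2, 1, 13))
        assert nir == 15 / 22
        assert round(p, 3) == 0.048

    def test_all_correct_tail_is_single_term(self):
        cm = ConfusionMatrix(3, 0, 0, 7)
        nir, p = nir_test(cm)
        assert p == pytest.approx(nir ** 10)

    def test_tail_matches_bruteforce_pmf_sum(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(2, 100))
            correct = int(rng.integers(0, n + 1))
            wrong = n - correct
            cm = ConfusionMatrix(tp=correct, fp=wrong, fn=0, tn=0)
            nir, p = nir_test(cm)
            brute = sum(stats.binom.pmf(k, n, nir) for k in range(correct, n + 1))
            assert p == pytest.approx(brute, abs=1e-12)


@pytest.fixture(scope="module")
def loco_cohort():
    cfg = SyntheticConfig(
        n_per_env=[40, 40, 40],
        prevalence_per_env=[0.3, 0.45, 0.6],
        gamma_per_env=[0.0, 1.5, 3.0],
        k_noise=10, seed=6,
    )
    return simulate_multicenter(cfg)


class TestScenarios:
    def test_loco_bookkeeping_and_partition(self, loco_cohort):
        table, meta, _ = loco_cohort
        result = run_loco(table, meta, recipes=FAST_RECIPES, seed=0, n_boot=100)
        # 3 environments x 2 recipes -> 6 reports
        assert sum(len(v) for v in result.reports.values()) == 6
        test_ids = [
            sid
            for e in meta.environments
            for sid, env in zip(meta.sample_ids, meta.environment)
            if env == e
        ]
        assert sorted(test_ids) == sorted(meta.sample_ids)  # disjoint cover
        for e, by_recipe in result.reports.items():
            n_e = meta.environment.count(e)
            for rep in by_recipe.values():
                assert rep.n_test == n_e
                assert rep.confusion_matrix.total == n_e

    def test_split_sizes_and_stratification(self, default_cohort):
        table, meta, _ = default_cohort
        result = run_split(table, meta, recipes=FAST_RECIPES[:1], seed=0, n_boot=100)
        rep = result.reports["split"]["A1"]
        # 70/30 of 77 under per-class rounding -> 53 train / 24 test
        assert rep.n_test == 24
        y = meta.y
        test_frac = rep.confusion_matrix.tp + rep.confusion_matrix.fn
        # class fraction in test within one sample's worth of the cohort's
        assert abs(test_frac / 24 - y.mean()) < 1 / 24

    def test_split_deterministic(self, default_cohort):
        table, meta, _ = default_cohort
        r1 = run_split(table, meta, recipes=FAST_RECIPES[:1], seed=4, n_boot=50)
        r2 = run_split(table, meta, recipes=FAST_RECIPES[:1], seed=4, n_boot=50)
        a = r1.reports["split"]["A1"].confusion_matrix
        b = r2.reports["split"]["A1"].confusion_matrix
        assert a == b

    def test_report_roundtrip(self, tmp_path, loco_cohort):
        table, meta, _ = loco_cohort
        result = run_loco(table, meta, recipes=FAST_RECIPES[1:], seed=0, n_boot=100)
        rep = next(iter(result.reports.values()))["B"]
        write_report(rep, tmp_path / "r.json")
        back = read_report(tmp_path / "r.json")
        assert back["confusion_matrix"] == rep.confusion_matrix.to_dict()
        assert back["nir_pvalue"] == rep.nir_pvalue


class TestSelectionFrequency:
    def _result(self, selected, names):
        return SelectionResult(
            method="lasso",
            selected=selected,
            diagnostics=np.zeros(len(names)),
            parameters={},
            feature_names=names,
        )

    def test_empty_results_give_empty_table(self):
        tab = selection_frequency_table([])
        assert tab.empty

    def test_incidence_vector_and_total(self):
        names = [f"original_firstorder_F{i}_T1_L1" for i in range(3)]
        incidence = [1, 1, 0, 1, 1, 1, 0, 0, 0, 0, 0, 1, 0, 1, 1]
        results = [self._result([0] if hit else [], names) for hit in incidence]
        tab = selection_frequency_table(results)
        assert tab.loc[names[0], "Total"] == 8

    def test_totals_match_bruteforce_recount(self):
        rng = np.random.default_rng(2)
        names = [f"original_firstorder_F{i}_T1_L1" for i in range(6)]
        results = [
            self._result(sorted(rng.choice(6, size=rng.integers(0, 5), replace=False).tolist()), names)
            for _ in range(9)
        ]
        tab = selection_frequency_table(results)
        for feat in tab.index:
            j = names.index(feat)
            brute = sum(j in r.selected for r in results)
            assert tab.loc[feat, "Total"] == brute
        assert list(tab["Total"]) == sorted(tab["Total"], reverse=True)
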