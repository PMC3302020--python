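import math

import numpy as np
import pytest

from strokecourse.cohort_model import DEATH, GOOD_VS_REST, POOR_VS_REST
from strokecourse.threshold_engine import (
    POSITIVE_IF_ABOVE,
    POSITIVE_IF_BELOW,
    CostSpec,
    InvalidCostError,
    ROCPoint,
    ThresholdCriterion,
    build_roc,
    delta_ratio,
    derive_thresholds,
    predictive_values,
    select_cutoff,
    target_slope,
)

from conftest import make_patient


def brute_force_best(scores, labels, S, orientation=POSITIVE_IF_ABOVE):
    """Exhaustive maximisation of Se - S(1-Sp) over all distinct cutoffs,
    written independently of the ROC machinery."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    n_pos, n_neg = y.sum(), len(y) - y.sum()
    distinct = np.unique(s)
    candidates = np.concatenate(
        ([distinct[0] - 1], (distinct[:-1] + distinct[1:]) / 2, [distinct[-1] + 1]))
    best = None
    for c in candidates:
        pred = s > c if orientation == POSITIVE_IF_ABOVE else s < c
        se = (pred & (y == 1)).sum() / n_pos
        sp = 1 - (pred & (y == 0)).sum() / n_neg
        j = se - S * (1 - sp)
        key = (j, sp, -se)
        if best is None or key > best:
            best = key
    return best


class TestDeltaRatio:
    @pytest.mark.parametrize("fp,rn,fn,rp,expected", [
        (3, 1, 2, 1, 2.0),   # the default doubled false-positive overcost
        (2, 1, 2, 1, 1.0),
        (5, 1, 3, 1, 2.0),
    ])
    def test_examples(self, fp, rn, fn, rp, expected):
        assert delta_ratio(CostSpec(fp, rn, fn, rp)) == pytest.approx(expected)

    def test_degenerate_costs_rejected(self):
        with pytest.raises(InvalidCostError):
            CostSpec(cost_FP=1, cost_RN=1, cost_FN=2, cost_RP=1)
        with pytest.raises(InvalidCostError):
            CostSpec(cost_FP=3, cost_RN=1, cost_FN=1, cost_RP=2)


class TestTargetSlope:
    @pytest.mark.parametrize("p,delta,expected", [
        (0.5, 2.0, 2.0),
        (0.2, 2.0, 8.0),
        (0.8, 1.0, 0.25),
    ])
    def test_examples(self, p, delta, expected):
        assert target_slope(p, delta) == pytest.approx(expected)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_prevalence_outside_unit_interval(self, p):
        with pytest.raises(ValueError):
            target_slope(p, 2.0)

    def test_criterion_consistency_enforced(self):
        with pytest.raises(ValueError):
            ThresholdCriterion(prevalence_p=0.5, delta=2.0, target_slope_S=3.0)


class TestBuildRoc:
    def test_separable_data_contains_perfect_point(self):
        pts = build_roc([1, 2, 3, 4], [0, 0, 1, 1], POSITIVE_IF_ABOVE)
        assert any(p.sensitivity == 1 and p.specificity == 1 for p in pts)

    def test_all_scores_equal_gives_only_endpoints(self):
        pts = build_roc([5, 5, 5, 5], [0, 1, 0, 1])
        assert len(pts) == 2
        ops = {(p.sensitivity, p.specificity) for p in pts}
        assert ops == {(0.0, 1.0), (1.0, 0.0)}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_roc([1, 2, 3], [1, 1, 1])

    def test_five_point_instance_against_enumeration(self):
        scores = [1, 2, 3, 10, 11]
        labels = [0, 0, 0, 1, 1]
        pts = build_roc(scores, labels, POSITIVE_IF_ABOVE)
        # one point per distinct score plus the two trivial endpoints
        assert len(pts) == 6
        s, y = np.array(scores, float), np.array(labels)
        for p in pts:
            pred = s > p.cutoff
            assert p.sensitivity == pytest.approx((pred & (y == 1)).sum() / 2)
            assert p.specificity == pytest.approx(1 - (pred & (y == 0)).sum() / 3)

    def test_curve_is_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(0)
        s = rng.normal(size=200) + np.repeat([0, 1], 100)
        y = np.repeat([0, 1], 100)
        pts = build_roc(s, y)
        fpr = [1 - p.specificity for p in pts]
        tpr = [p.sensitivity for p in pts]
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1
        assert all(b >= a for a, b in zip(fpr, fpr[1:]))
        assert all(b >= a for a, b in zip(tpr, tpr[1:]))

    def test_matches_sklearn_operating_points(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(5)
        s = np.round(rng.normal(size=300), 1) + np.repeat([0.0, 1.5], 150)
        y = np.repeat([0, 1], 150)
        fpr, tpr, _ = sk.roc_curve(y, s, drop_intermediate=False)
        ours = {(round(1 - p.specificity, 10), round(p.sensitivity, 10))
                for p in build_roc(s, y)}
        theirs = {(round(f, 10), round(t, 10)) for f, t in zip(fpr, tpr)}
        assert ours == theirs


class TestSelectCutoff:
    def test_separable_picks_perfect_point(self):
        pts = build_roc([1, 2, 3, 4], [0, 0, 1, 1])
        for S in (0.5, 2.0, 10.0):
            res = select_cutoff(pts, ThresholdCriterion.from_prevalence(
                1 / (1 + S / 2), 2.0))
            assert res.sensitivity == 1 and res.specificity == 1
            assert res.ppv == 1 and res.npv == 1

    def test_five_point_instance_midpoint_cutoff(self):
        pts = build_roc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1])
        crit = ThresholdCriterion(prevalence_p=0.4, delta=2.0,
                                  target_slope_S=3.0)
        res = select_cutoff(pts, crit)
        assert res.cutoff == pytest.approx(6.5)  # midpoint between 3 and 10
        assert res.sensitivity == 1 and res.specificity == 1
        assert res.sensitivity - 3.0 * (1 - res.specificity) == pytest.approx(1.0)

    def test_tie_breaks_toward_higher_specificity(self):
        # two points with identical objective; prefer the specific one
        roc = [ROCPoint(1.5, 0.5, 1.0), ROCPoint(0.5, 1.0, 0.5)]
        crit = ThresholdCriterion.from_prevalence(0.5, 1.0)  # S = 1
        res = select_cutoff(roc, crit)
        assert res.specificity == 1.0 and res.cutoff == 1.5

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(100):
            n = int(rng.integers(5, 80))
            s = rng.integers(0, 10, n).astype(float)  # heavy ties
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            orient = POSITIVE_IF_ABOVE if rng.random() < 0.5 else POSITIVE_IF_BELOW
            p = float(rng.uniform(0.1, 0.9))
            crit = ThresholdCriterion.from_prevalence(p, float(rng.uniform(0.5, 4)))
            res = select_cutoff(build_roc(s, y, orient), crit, orient)
            j = res.sensitivity - crit.target_slope_S * (1 - res.specificity)
            best_j, best_sp, neg_se = brute_force_best(s, y, crit.target_slope_S, orient)
            assert j == pytest.approx(best_j, abs=1e-12)
            assert res.specificity == pytest.approx(best_sp, abs=1e-12)


class TestPredictiveValues:
    def test_perfect_test(self):
        for p in (0.1, 0.5, 0.9):
            assert predictive_values(p, 1, 1) == (1, 1)

    def test_hand_worked_example(self):
        ppv, npv = predictive_values(0.5, 0.8, 0.9)
        assert ppv == pytest.approx(0.8889, abs=5e-5)
        assert npv == pytest.approx(0.8182, abs=5e-5)

    def test_rare_disease_limit(self):
        ppv, npv = predictive_values(1e-9, 0.8, 0.9)
        assert ppv < 1e-7 and npv > 1 - 1e-7

    def test_undefined_denominators_flagged_not_raised(self):
        ppv, npv = predictive_values(0.5, 0.0, 1.0)
        assert ppv is None and npv is not None
        ppv, npv = predictive_values(0.5, 1.0, 0.0)
        assert npv is None and ppv is not None

    def test_monotone_in_prevalence_sensitivity_specificity(self):
        grid = np.linspace(0.05, 0.95, 10)
        for se, sp in ((0.7, 0.8), (0.9, 0.6)):
            ppvs = [predictive_values(p, se, sp)[0] for p in grid]
            npvs = [predictive_values(p, se, sp)[1] for p in grid]
            assert all(b >= a for a, b in zip(ppvs, ppvs[1:]))
            assert all(b <= a for a, b in zip(npvs, npvs[1:]))
        for se in grid:
            assert (predictive_values(0.3, se, 0.8)[0]
                    <= predictive_values(0.3, min(se + 0.05, 1), 0.8)[0])
        for sp in grid[:-1]:
            assert (predictive_values(0.3, 0.8, sp)[0]
                    <= predictive_values(0.3, 0.8, sp + 0.05)[0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            predictive_values(0.5, 1.2, 0.5)


class TestDeriveThresholds:
    def _perfect_cohort(self):
        # predictor separates the outcome exactly
        cohort = []
        for i in range(20):
            cohort.append(make_patient([2, 2], mrs=0, anamnesis=60,
                                       pid=f"G{i}"))
        for i in range(20):
            cohort.append(make_patient([30, 30], mrs=DEATH, anamnesis=1300,
                                       pid=f"D{i}"))
        return cohort

    def test_perfect_predictor_gives_perfect_threshold(self):
        cohort = self._perfect_cohort()
        for dichotomy, orient in ((GOOD_VS_REST, POSITIVE_IF_BELOW),
                                  (POOR_VS_REST, POSITIVE_IF_ABOVE)):
            res = derive_thresholds(cohort, dichotomy, predictor="nihss_initial")
            assert res.orientation == orient
            assert res.sensitivity == 1 and res.specificity == 1
            assert res.ppv == 1 and res.npv == 1
            assert 2 < res.cutoff < 30

    def test_poor_outcome_cutoff_in_high_severity_region(self, big_cohort):
        res = derive_thresholds(big_cohort, POOR_VS_REST,
                                predictor="nihss_initial")
        assert res.cutoff >= 15
        assert res.ppv is not None and res.npv is not None

    def test_custom_costs_equal_explicit_delta(self, small_cohort):
        by_costs = derive_thresholds(small_cohort, POOR_VS_REST,
                                     costs=CostSpec(3, 1, 2, 1))
        by_delta = derive_thresholds(small_cohort, POOR_VS_REST, delta=2.0)
        assert by_costs == by_delta

    def test_permuted_labels_give_near_chance_objective(self, big_cohort):
        """With outcome labels shuffled the cost-weighted objective has no
        signal: its maximum stays near the chance-diagonal value of 0."""
        import numpy as np

        from strokecourse.cohort_model import dichotomize
        from strokecourse.threshold_engine import predictor_values

        rng = np.random.default_rng(99)
        scores = predictor_values(big_cohort[:2000], "nihss_initial")
        labels = np.array([dichotomize(r.mrs_discharge, POOR_VS_REST)
                           for r in big_cohort[:2000]])
        p = labels.mean()
        crit = ThresholdCriterion.from_prevalence(float(p), 2.0)
        js = []
        for _ in range(10):
            perm = rng.permutation(labels)
            res = select_cutoff(build_roc(scores, perm), crit)
            js.append(res.sensitivity - crit.target_slope_S * (1 - res.specificity))
        # true-label objective for contrast
        res_true = select_cutoff(build_roc(scores, labels), crit)
        j_true = res_true.sensitivity - crit.target_slope_S * (1 - res_true.specificity)
        assert max(js) < 0.5 * j_true
        assert np.mean(js) < 0.15
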