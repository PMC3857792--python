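"""ROC/AUC machinery, Hanley-McNeil intervals, cut-point selection, test
characteristics and the baseline comparison tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dehydrakit.evaluation import (
    ContingencyTable,
    ROCCurve,
    auc_ci_hanley,
    auc_mann_whitney,
    best_cutpoint,
    chi_square_test,
    empirical_roc,
    impression_characteristics,
    is_significant_predictor,
    lr_from_rates,
    mann_whitney_test,
    round_lr,
    subgroup_report,
    test_characteristics as accuracy_characteristics,
)


def pairwise_auc(scores, outcomes):
    """Brute-force oracle: wins + half-ties over all positive-negative pairs."""
    pos = [s for s, y in zip(scores, outcomes) if y == 1]
    neg = [s for s, y in zip(scores, outcomes) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


score_outcome_instances = st.integers(5, 40).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 8), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda y: 0 < sum(y) < len(y)
        ),
    )
)


class TestAUC:
    def test_perfect_separation(self):
        with pytest.warns(UserWarning):
            roc = empirical_roc([1, 2, 3], [0, 0, 1])
        assert roc.auc == 1.0

    def test_all_ties_is_chance(self):
        assert auc_mann_whitney([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_small_instance_matches_pair_enumeration(self):
        scores, outcomes = [3, 1, 2, 2], [1, 0, 0, 1]
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(
            pairwise_auc(scores, outcomes)
        )

    def test_label_swap_antisymmetry(self, rng):
        scores = rng.integers(0, 10, 50)
        outcomes = rng.integers(0, 2, 50)
        outcomes[0], outcomes[1] = 1, 0
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(
            1.0 - auc_mann_whitney(scores, 1 - outcomes)
        )

    @settings(max_examples=300, derandomize=True)
    @given(score_outcome_instances)
    def test_trapezoid_equals_mann_whitney_and_oracle(self, inst):
        scores, outcomes = inst
        roc = empirical_roc(scores, outcomes)
        fpr = 1.0 - roc.specificity
        order = np.lexsort((roc.sensitivity, fpr))  # staircase vertex order
        trap = float(np.trapezoid(roc.sensitivity[order], fpr[order]))
        assert abs(trap - roc.auc) < 1e-12
        assert roc.auc == pytest.approx(pairwise_auc(scores, outcomes), abs=1e-12)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            scores = rng.integers(0, 9, 60)
            y = (rng.random(60) < 0.3).astype(int)
            y[:2] = [0, 1]
            assert auc_mann_whitney(scores, y) == pytest.approx(
                roc_auc_score(y, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            auc_mann_whitney([1, 2], [0, 0])
        with pytest.raises(ValueError, match="negative"):
            auc_mann_whitney([1, 2], [1, 1])

    def test_roc_monotone_sensitivity(self, rng):
        roc = empirical_roc(rng.integers(0, 9, 80), np.r_[np.ones(20, int), np.zeros(60, int)])
        assert (np.diff(roc.sensitivity) <= 1e-12).all()  # thresholds ascend
        assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
        assert roc.sensitivity[-1] == 0.0 and roc.specificity[-1] == 1.0


class TestHanleyCI:
    def test_closed_form_at_half(self):
        n = 20
        se, _ = auc_ci_hanley(0.5, n, n)
        expected = math.sqrt((0.25 + (n - 1) * (1 / 3 - 0.25) * 2) / n**2)
        assert se == pytest.approx(expected, abs=1e-15)

    def test_direct_formula_evaluation(self):
        a, n1, n0 = 0.8, 13, 127
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        expected = math.sqrt(
            (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0)
        )
        se, (lo, hi) = auc_ci_hanley(a, n1, n0)
        assert se == pytest.approx(expected, abs=1e-15)
        assert lo == pytest.approx(a - 1.96 * se) and hi == pytest.approx(a + 1.96 * se)

    def test_single_pair_reduces_to_bernoulli(self):
        se, _ = auc_ci_hanley(0.7, 1, 1)
        assert se == pytest.approx(math.sqrt(0.7 * 0.3))

    def test_degenerate_auc_warns_with_zero_se(self):
        with pytest.warns(UserWarning):
            se, ci = auc_ci_hanley(1.0, 5, 5)
        assert se == 0.0 and ci == (1.0, 1.0)

    def test_ci_clipped_to_unit_interval(self):
        _, (lo, hi) = auc_ci_hanley(0.95, 3, 3)
        assert 0.0 <= lo and hi <= 1.0


def _roc_stub(points, auc=0.8, ci=(0.6, 0.9)):
    t, se, sp = zip(*points)
    return ROCCurve(np.array(t, float), np.array(se), np.array(sp), auc, 0.05, ci, 10, 100)


class TestSignificance:
    @pytest.mark.parametrize(
        "ci, expected", [((0.71, 0.89), True), ((0.47, 0.833), False), ((0.5, 0.9), False)]
    )
    def test_ci_strictly_above_chance(self, ci, expected):
        roc = _roc_stub([(1, 1.0, 0.0)], ci=ci)
        assert is_significant_predictor(roc) is expected


class TestBestCutpoint:
    def test_maximizes_sensitivity_above_floor(self):
        roc = _roc_stub([(2, 0.67, 0.68), (3, 0.40, 0.85)])
        assert best_cutpoint(roc) == 2

    def test_no_feasible_threshold_errors(self):
        roc = _roc_stub([(1, 1.0, 0.2), (2, 0.9, 0.5)])
        with pytest.raises(ValueError, match="floor"):
            best_cutpoint(roc, 0.5)

    def test_sensitivity_tie_broken_by_specificity(self):
        roc = _roc_stub([(1, 1.0, 0.54), (2, 1.0, 0.60)])
        assert best_cutpoint(roc) == 2

    def test_full_tie_broken_by_lower_threshold(self):
        roc = _roc_stub([(1, 0.9, 0.6), (2, 0.9, 0.6)])
        assert best_cutpoint(roc) == 1

    @settings(max_examples=200, derandomize=True)
    @given(score_outcome_instances, st.floats(0.0, 0.9))
    def test_never_violates_floor_and_monotone_in_floor(self, inst, floor):
        scores, outcomes = inst
        roc = empirical_roc(scores, outcomes)
        try:
            cut = best_cutpoint(roc, floor)
        except ValueError:
            return
        i = int(np.where(roc.thresholds == cut)[0][0])
        assert roc.specificity[i] > floor
        sens_at = roc.sensitivity[i]
        higher = min(floor + 0.2, 0.95)
        try:
            cut2 = best_cutpoint(roc, higher)
        except ValueError:
            return
        j = int(np.where(roc.thresholds == cut2)[0][0])
        assert roc.sensitivity[j] <= sens_at + 1e-12


class TestTestCharacteristics:
    def test_perfectly_sensitive_scale_row(self):
        # 13 outcome-positive children all detected; 69/127 negatives correct
        tc = accuracy_characteristics(ContingencyTable(tp=13, fp=58, fn=0, tn=69))
        assert tc.sensitivity == 1.0
        assert tc.specificity == pytest.approx(69 / 127)
        assert round_lr(tc.lr_pos) == 2.2
        assert tc.lr_pos_ci[0] == pytest.approx(1.8, abs=0.05)
        assert tc.lr_pos_ci[1] == pytest.approx(2.6, abs=0.05)
        assert tc.lr_neg == 0.0 and tc.lr_neg_ci is None  # reported as NC
        # boundary sensitivity: exact (Clopper-Pearson) lower bound, not Wald
        assert tc.sensitivity_ci[0] == pytest.approx(
            stats.beta.ppf(0.025, 13, 1), abs=1e-9
        )
        assert 0.70 < tc.sensitivity_ci[0] < 0.78 and tc.sensitivity_ci[1] == 1.0

    def test_uninformative_table(self):
        tc = accuracy_characteristics(ContingencyTable(25, 25, 25, 25))
        assert tc.sensitivity == tc.specificity == 0.5
        assert tc.lr_pos == pytest.approx(1.0) and tc.lr_neg == pytest.approx(1.0)

    def test_interior_table_against_direct_arithmetic(self):
        tc = accuracy_characteristics(ContingencyTable(tp=8, fp=41, fn=4, tn=86))
        se, sp = 8 / 12, 86 / 127
        assert tc.sensitivity == pytest.approx(se) and tc.specificity == pytest.approx(sp)
        assert tc.lr_pos == pytest.approx(se / (1 - sp))
        assert tc.lr_neg == pytest.approx((1 - se) / sp)
        var_pos = (1 - se) / (se * 12) + sp / ((1 - sp) * 127)
        assert tc.lr_pos_ci[1] / tc.lr_pos_ci[0] == pytest.approx(
            math.exp(2 * 1.959963984540054 * math.sqrt(var_pos)), rel=1e-9
        )

    def test_lr_identities_match_rate_derived_values(self, rng):
        for _ in range(50):
            t = ContingencyTable(*(int(x) for x in rng.integers(1, 60, 4)))
            tc = accuracy_characteristics(t)
            lp, ln = lr_from_rates(tc.sensitivity, tc.specificity)
            assert tc.lr_pos == pytest.approx(lp) and tc.lr_neg == pytest.approx(ln)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            accuracy_characteristics(ContingencyTable(0, 3, 0, 4))


class TestLRFromRates:
    @pytest.mark.parametrize(
        "se, sp, exp_pos, exp_neg",
        [
            (0.67, 0.68, 2.1, 0.5),
            (1.00, 0.54, 2.2, 0.0),
            (0.5, 0.5, 1.0, 1.0),
            (0.83, 0.58, 2.0, 0.3),
        ],
    )
    def test_rounded_point_values(self, se, sp, exp_pos, exp_neg):
        lp, ln = lr_from_rates(se, sp)
        assert round_lr(lp) == exp_pos and round_lr(ln) == exp_neg

    def test_degenerate_rates_flagged_nc(self):
        assert lr_from_rates(0.9, 1.0)[0] is None
        assert lr_from_rates(0.9, 0.0)[1] is None


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        _, p = mann_whitney_test([1.0, 2.0, 3.0] * 5, [1.0, 2.0, 3.0] * 5)
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact(self):
        u, p = mann_whitney_test([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
        assert u == 25.0
        assert p == pytest.approx(2 / math.comb(10, 5))

    def test_exact_path_agrees_with_full_enumeration_under_ties(self):
        x, y = [1.0, 2.0, 2.0, 5.0], [2.0, 3.0, 4.0]
        u_obs, p = mann_whitney_test(x, y)
        combined = x + y
        ranks = stats.rankdata(combined)
        n1 = len(x)
        mu = n1 * len(y) / 2
        devs = [
            abs(sum(ranks[list(idx)]) - n1 * (n1 + 1) / 2 - mu)
            for idx in itertools.combinations(range(len(combined)), n1)
        ]
        d_obs = abs(u_obs - mu)
        expected = sum(d >= d_obs - 1e-12 for d in devs) / len(devs)
        assert p == pytest.approx(expected)

    def test_u_statistic_identity(self, rng):
        x, y = rng.normal(0, 1, 15), rng.normal(0.5, 1, 12)
        ux, _ = mann_whitney_test(x, y)
        uy, _ = mann_whitney_test(y, x)
        assert ux + uy == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_test([], [1.0])


class TestChiSquare:
    def test_proportional_table_null(self):
        stat, p = chi_square_test([[10, 20], [30, 60]])
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_direct_formula_expansion(self):
        obs = np.array([[10, 90], [20, 80]], float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / n
        by_hand = float(((obs - expected) ** 2 / expected).sum())
        stat, p = chi_square_test(obs)
        assert stat == pytest.approx(by_hand)
        assert p == pytest.approx(stats.chi2.sf(by_hand, 1))

    def test_swap_invariance(self):
        t = [[10, 90], [20, 80]]
        assert chi_square_test(t)[0] == pytest.approx(chi_square_test([r[::-1] for r in t])[0])
        assert chi_square_test(t)[0] == pytest.approx(chi_square_test(t[::-1])[0])

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_test([[0, 0], [5, 5]])


class TestSubgroups:
    def _df(self, rng, n=600, informative=True):
        import pandas as pd

        y = (rng.random(n) < 0.2).astype(int)
        base = y * 2.0 if informative else 0.0
        return pd.DataFrame(
            {
                "score": rng.normal(base, 1.0, n).round(1),
                "outcome": y,
                "provider": rng.choice(["nurse", "physician"], n),
                "age_months": rng.uniform(1, 36, n),
            }
        )

    def test_provider_independent_signs_give_similar_stratum_aucs(self, rng):
        df = self._df(rng)
        rep = subgroup_report(df, "provider", {"S": "score"}, "outcome")
        pooled = subgroup_report(df, "none", {"S": "score"}, "outcome")["auc"].iloc[0]
        for _, row in rep.iterrows():
            assert abs(row["auc"] - pooled) < 3 * row["se"]

    def test_single_class_stratum_flagged_not_computed(self, rng):
        df = self._df(rng, n=40)
        df.loc[df["provider"] == "nurse", "outcome"] = 0
        rep = subgroup_report(df, "provider", {"S": "score"}, "outcome")
        nurse = rep[rep["stratum"] == "nurse"].iloc[0]
        assert nurse["flag"] == "single-outcome-class" and np.isnan(nurse["auc"])

    def test_exact_boundary_age_goes_to_older_stratum(self, rng):
        df = self._df(rng, n=50)
        df["age_months"] = 12.0
        rep = subgroup_report(df, "age", {"S": "score"}, "outcome")
        under = rep[rep["stratum"] == "under_12m"].iloc[0]
        over = rep[rep["stratum"] == "over_12m"].iloc[0]
        assert under["n"] == 0 and over["n"] == 50


class TestImpression:
    def test_weak_impression_not_significant(self):
        # LR+ interval spanning 1 -> not a significant predictor
        tc = accuracy_characteristics(ContingencyTable(tp=4, fp=20, fn=9, tn=107))
        assert tc.lr_pos_ci[0] < 1.0 < tc.lr_pos_ci[1]
        assert tc.lr_pos_significant() is False

    def test_perfect_impression_degenerate(self):
        y = [1] * 5 + [0] * 20
        tc = impression_characteristics(y, y)
        assert tc.lr_pos is None  # specificity 1 -> NC
        assert tc.lr_neg == 0.0 and tc.lr_neg_ci is None

    def test_independent_impression_lr_near_one(self, rng):
        n = 20000
        y = (rng.random(n) < 0.3).astype(int)
        imp = (rng.random(n) < 0.4).astype(int)
        tc = impression_characteristics(imp, y)
        assert tc.lr_pos == pytest.approx(1.0, abs=0.05)
        assert tc.lr_neg == pytest.approx(1.0, abs=0.05)
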