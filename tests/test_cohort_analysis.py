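import math

import numpy as np
import pytest
from scipy import stats

from oracles import (hand_kaplan_meier, hand_logrank_chi2, hand_paired_t,
                     hand_spearman)
from aluedit.errors import ValidationError
from aluedit.cohort_analysis import (
    AnalysisParams, CohortRecord, covariate_panel, dichotomize_aei,
    kaplan_meier, logrank_test, median_survival, phase_comparison,
    spearman_gaussian,
)


def _rec(pid, aei, weeks=10.0, event=1, phase="pre", **kw):
    return CohortRecord(patient_id=pid, phase=phase, survival_weeks=weeks,
                        event=event, aei=aei, **kw)


# ---------------------------------------------------------------------------
# Spearman

class TestSpearmanGaussian:
    def test_perfect_monotone(self):
        r, p = spearman_gaussian([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_perfect_inverse(self):
        r, _ = spearman_gaussian([1, 2, 3, 4], [30, 20, 10, 0])
        assert r == pytest.approx(-1.0)

    def test_hand_rank_formula(self):
        x, y = (1, 2, 3, 4, 5), (2, 1, 4, 3, 5)
        r, _ = spearman_gaussian(x, y)
        assert r == pytest.approx(hand_spearman(x, y))
        assert r == pytest.approx(0.8)  # 1 - 6*4/120, no ties

    def test_gaussian_p_formula(self):
        x, y = (1, 2, 3, 4, 5), (2, 1, 4, 3, 5)
        r, p = spearman_gaussian(x, y)
        assert p == pytest.approx(2 * stats.norm.sf(abs(r) * math.sqrt(4)))

    def test_t_approximation_flag(self):
        x, y = (1, 2, 3, 4, 5), (2, 1, 4, 3, 5)
        r, p = spearman_gaussian(x, y, approximation="t")
        t = abs(r) * math.sqrt(3 / (1 - r * r))
        assert p == pytest.approx(2 * stats.t.sf(t, df=3))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            spearman_gaussian([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValidationError):
            spearman_gaussian([1, 2, 3], [1, 2, 3])

    def test_monotone_transform_invariance(self, rng):
        for _ in range(25):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            r1, p1 = spearman_gaussian(x, y)
            r2, p2 = spearman_gaussian(np.exp(x), y ** 3)
            assert r1 == pytest.approx(r2)
            assert p1 == pytest.approx(p2)

    def test_matches_scipy_r(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30) + 0.5 * x
        r, _ = spearman_gaussian(x, y)
        assert r == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_r_bounded(self, rng):
        for _ in range(20):
            x = rng.integers(0, 5, size=10).astype(float)  # ties allowed
            y = rng.integers(0, 5, size=10).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = spearman_gaussian(x, y)
            assert -1.0 <= r <= 1.0 and 0.0 <= p <= 1.0


# ---------------------------------------------------------------------------
# Dichotomization

class TestDichotomizeAei:
    def test_partition_at_cutoff(self):
        records = [_rec("a", 10), _rec("b", 49.9), _rec("c", 50.1), _rec("d", 90)]
        low, high = dichotomize_aei(records)
        assert [r.aei for r in low] == [10, 49.9]
        assert [r.aei for r in high] == [50.1, 90]

    def test_exact_cutoff_goes_high_by_default(self):
        low, high = dichotomize_aei([_rec("a", 50.0)])
        assert low == [] and len(high) == 1

    def test_exact_cutoff_configurable(self):
        params = AnalysisParams(equal_to_cutoff_goes="low")
        low, high = dichotomize_aei([_rec("a", 50.0)], params)
        assert len(low) == 1 and high == []

    def test_all_below_cutoff(self):
        low, high = dichotomize_aei([_rec("a", 1), _rec("b", 2)])
        assert len(low) == 2 and high == []

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            dichotomize_aei([])


# ---------------------------------------------------------------------------
# Kaplan-Meier

class TestKaplanMeier:
    def test_two_events_by_hand(self):
        curve = kaplan_meier([5, 10], [1, 1])
        assert curve.times == [5, 10]
        assert curve.survival == pytest.approx([0.5, 0.0])
        assert curve.at_risk == [2, 1]

    def test_all_censored_flat_at_one(self):
        curve = kaplan_meier([3, 6, 9], [0, 0, 0])
        assert curve.times == []
        assert curve.survival_at(100) == 1.0

    def test_five_observation_hand_example(self):
        # times (2,4,4,7,9), events (1,1,0,1,1):
        # S = 4/5 -> 4/5*3/4 = 3/5 -> 3/5*1/2 = 3/10 -> 0
        curve = kaplan_meier([2, 4, 4, 7, 9], [1, 1, 0, 1, 1])
        expected = hand_kaplan_meier([2, 4, 4, 7, 9], [1, 1, 0, 1, 1])
        assert curve.times == [t for t, _, _, _ in expected]
        assert curve.survival == pytest.approx([s for _, s, _, _ in expected])
        assert curve.survival == pytest.approx([0.8, 0.6, 0.3, 0.0])
        assert curve.at_risk == [5, 4, 2, 1]

    def test_non_increasing_starts_at_one(self, rng):
        times = rng.exponential(10, size=40)
        events = rng.integers(0, 2, size=40)
        if events.sum() == 0:
            events[0] = 1
        curve = kaplan_meier(times, events)
        assert all(s1 >= s2 for s1, s2 in zip(curve.survival, curve.survival[1:]))
        assert curve.survival_at(-1) == 1.0
        assert all(0.0 <= s <= 1.0 for s in curve.survival)

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        times = np.round(rng.exponential(10, size=30), 1)
        curve = kaplan_meier(times, np.ones(30, dtype=int))
        for t in curve.times:
            ecdf = np.mean(times <= t)
            assert curve.survival_at(t) == pytest.approx(1 - ecdf)

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = np.round(rng.exponential(10, size=50), 2)
        events = rng.integers(0, 2, size=50)
        events[0] = 1
        curve = kaplan_meier(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]))


class TestMedianSurvival:
    def test_exact_half_step(self):
        curve = kaplan_meier([10, 30], [1, 1])  # S: 0.5 at t=10
        assert median_survival(curve) == 10

    def test_not_reached_when_all_censored(self):
        curve = kaplan_meier([3, 6], [0, 0])
        assert median_survival(curve) is None

    def test_hand_example(self):
        curve = kaplan_meier([2, 4, 4, 7, 9], [1, 1, 0, 1, 1])
        # first step with S <= 0.5 is t=7 (S=0.3)
        assert median_survival(curve) == 7


# ---------------------------------------------------------------------------
# Log-rank

class TestLogrank:
    def test_identical_groups_zero(self):
        g = ([1, 2, 3], [1, 1, 1])
        chi2, p, df = logrank_test(g, g)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_toy_matches_hand_accumulation(self):
        a = ([1, 2], [1, 1])
        b = ([3, 4], [1, 1])
        chi2, p, _ = logrank_test(a, b)
        expected = hand_logrank_chi2(*a, *b)
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert chi2 == pytest.approx(49 / 17)  # hand O/E/Var table

    def test_label_swap_invariance(self, rng):
        a = (rng.exponential(10, size=15), rng.integers(0, 2, size=15))
        b = (rng.exponential(15, size=12), rng.integers(0, 2, size=12))
        a[1][0] = 1
        b[1][0] = 1
        chi2_ab, p_ab, _ = logrank_test(a, b)
        chi2_ba, p_ba, _ = logrank_test(b, a)
        assert chi2_ab == pytest.approx(chi2_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        ta = np.round(rng.exponential(10, size=25), 2)
        tb = np.round(rng.exponential(20, size=25), 2)
        ea = rng.integers(0, 2, size=25)
        eb = rng.integers(0, 2, size=25)
        ea[0] = eb[0] = 1
        chi2, p, _ = logrank_test((ta, ea), (tb, eb))
        result = ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
        assert chi2 == pytest.approx(result.test_statistic)
        assert p == pytest.approx(result.p_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(([], []), ([1], [1]))


# ---------------------------------------------------------------------------
# Phase comparison

class TestPhaseComparison:
    def test_identical_groups_p_one(self):
        pre = [_rec(f"p{i}", 30 + i) for i in range(5)]
        on = [_rec(f"p{i}", 30 + i, phase="on") for i in range(5)]
        result = phase_comparison(pre, on)
        assert result["unpaired_p"] == pytest.approx(1.0)
        assert result["paired_p"] == pytest.approx(1.0)

    def test_constant_shift_zero_variance_rule(self):
        pre = [_rec(f"p{i}", v) for i, v in enumerate((1, 2, 3))]
        on = [_rec(f"p{i}", v, phase="on") for i, v in enumerate((2, 3, 4))]
        result = phase_comparison(pre, on)
        # all paired differences are exactly -1: documented p = 0
        assert result["paired_p"] == 0.0
        assert result["n_pairs"] == 3

    def test_paired_matches_hand_formula(self, rng):
        pre_vals = 48 + 27 * rng.normal(size=23)
        on_vals = pre_vals + 10 + 27 * rng.normal(size=23)
        pre = [_rec(f"p{i}", max(v, 0.1)) for i, v in enumerate(pre_vals)]
        on = [_rec(f"p{i}", max(v, 0.1), phase="on")
              for i, v in enumerate(on_vals)]
        result = phase_comparison(pre, on)
        diffs = [a.aei - b.aei for a, b in zip(pre, on)]
        _, p_hand = hand_paired_t(diffs)
        assert result["paired_p"] == pytest.approx(p_hand)

    def test_unpaired_is_welch(self, rng):
        pre = [_rec(f"p{i}", v) for i, v in
               enumerate(np.abs(rng.normal(48, 27, size=10)))]
        on = [_rec(f"p{i}", v, phase="on") for i, v in
              enumerate(np.abs(rng.normal(59, 35, size=12)))]
        result = phase_comparison(pre, on)
        expected = stats.ttest_ind([r.aei for r in pre], [r.aei for r in on],
                                   equal_var=False).pvalue
        assert result["unpaired_p"] == pytest.approx(expected)
        assert result["pre_sd"] == pytest.approx(
            np.std([r.aei for r in pre], ddof=1))

    def test_too_few_pairs_rejected(self):
        pre = [_rec("a", 10), _rec("b", 20)]
        on = [_rec("a", 15, phase="on"), _rec("zz", 25, phase="on")]
        with pytest.raises(ValidationError, match="pairs"):
            phase_comparison(pre, on)


# ---------------------------------------------------------------------------
# Covariate panel

class TestCovariatePanel:
    def test_identity_covariate_r_one(self):
        records = [_rec(f"p{i}", 10.0 * (i + 1), mutation_load=10.0 * (i + 1))
                   for i in range(8)]
        panel_a, _ = covariate_panel(records, covariates=["mutation_load"])
        assert panel_a.iloc[0].spearman_r == pytest.approx(1.0)

    def test_constant_covariate_flagged(self):
        records = [_rec(f"p{i}", 10.0 * (i + 1), mutation_load=7.0)
                   for i in range(8)]
        panel_a, _ = covariate_panel(records, covariates=["mutation_load"])
        assert panel_a.iloc[0].note == "constant-covariate"
        assert np.isnan(panel_a.iloc[0].spearman_r)

    def test_insufficient_pairs_flagged(self):
        records = [_rec(f"p{i}", 10.0 * (i + 1),
                        mutation_load=5.0 + i if i < 3 else None)
                   for i in range(8)]
        panel_a, _ = covariate_panel(records, covariates=["mutation_load"])
        assert panel_a.iloc[0].note == "insufficient-data"

    def test_group_means_and_welch_p(self, rng):
        records = []
        for i in range(20):
            aei = 20.0 if i < 10 else 80.0
            records.append(_rec(f"p{i}", aei,
                                mutation_load=float(rng.lognormal(5, 1))))
        _, panel_b = covariate_panel(records, covariates=["mutation_load"])
        row = panel_b.iloc[0]
        lo = [r.mutation_load for r in records if r.aei < 50]
        hi = [r.mutation_load for r in records if r.aei > 50]
        assert row.low_mean == pytest.approx(np.mean(lo))
        assert row.high_sd == pytest.approx(np.std(hi, ddof=1))
        assert row.p == pytest.approx(
            stats.ttest_ind(lo, hi, equal_var=False).pvalue)

    def test_cytolytic_score_row_uses_geometric_mean(self):
        records = [_rec(f"p{i}", 10.0 * (i + 1), gzma_expr=4.0, prf1_expr=9.0)
                   for i in range(6)]
        panel_a, _ = covariate_panel(records, covariates=["cytolytic_score"])
        # constant geometric mean 6 -> constant covariate
        assert panel_a.iloc[0].note == "constant-covariate"

    def test_type_one_error_rate(self, rng):
        """Independent covariate: |r| rejects at ~5% under the Gaussian
        approximation (n=22, as in the published panel)."""
        n, reps, alpha = 22, 400, 0.05
        rejections = 0
        for _ in range(reps):
            aei = rng.gamma(3.16, 15.2, size=n)
            cov = rng.lognormal(5, 1, size=n)
            _, p = spearman_gaussian(aei, cov)
            rejections += p < alpha
        rate = rejections / reps
        # binomial 99.9% envelope around 0.05 (gaussian approx is slightly
        # liberal at n=22, so allow a widened upper bound)
        assert 0.01 <= rate <= 0.12
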