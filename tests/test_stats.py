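"""Contingency, survival, and model-selection statistics.

Frozen expected values for the 2×2 rows come from the published cohort
demographics table; independent oracles (hypergeometric enumeration, a
hand-computed product-limit table, an observed-minus-expected log-rank,
exhaustive subset AIC, all-pairs concordance counting, permutation
enumeration) guard each estimator.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from phbrkit.errors import (
    ArityError,
    DegenerateModelError,
    DomainError,
    EmptyInputError,
    UndefinedEstimateError,
)
from phbrkit.stats import (
    ContingencyTable2x2,
    auroc,
    backward_aic_logistic,
    cox_ph,
    fisher_exact,
    km_fit,
    log_rank,
    mann_whitney,
    risk_ratio,
    spearman,
)

# Cohort demographics rows that reproduce from their printed counts:
# (a, b, c, d, RR, CI low, CI high) at two decimals.
TABLE1_ROWS = {
    "sex_male_vs_female": (22, 24, 10, 27, 1.77, 0.96, 3.26),
    "ethnicity": (27, 44, 5, 7, 0.91, 0.44, 1.90),
    "age_lt60_vs_ge60": (6, 11, 26, 40, 0.90, 0.44, 1.82),
    "nsclc_vs_others": (7, 19, 25, 32, 0.61, 0.31, 1.23),
    "other_tumors": (14, 24, 18, 27, 0.92, 0.53, 1.60),
    "tmb_lt20_vs_ge20": (18, 38, 11, 10, 0.61, 0.35, 1.07),
    "tmb_lt10_vs_ge10": (11, 27, 18, 21, 0.63, 0.34, 1.15),
    "therapy_mono_vs_combo": (26, 40, 6, 11, 1.12, 0.55, 2.27),
    "benefit_vs_others": (17, 19, 15, 31, 1.45, 0.84, 2.49),
    "pd_vs_others": (7, 25, 25, 26, 0.45, 0.22, 0.91),
}


class TestRiskRatio:
    @pytest.mark.parametrize("label", sorted(TABLE1_ROWS))
    def test_printed_rows_reproduce(self, label):
        # agreement at the printed two-decimal precision (half a unit in the
        # last place; the published table rounds intermediate values, so a
        # bound can sit exactly on the rounding boundary)
        a, b, c, d, rr, lo, hi = TABLE1_ROWS[label]
        res = risk_ratio(ContingencyTable2x2(a, b, c, d))
        assert res.rr == pytest.approx(rr, abs=0.0055)
        assert res.ci_low == pytest.approx(lo, abs=0.0055)
        assert res.ci_high == pytest.approx(hi, abs=0.0055)

    def test_equal_risks_give_unity(self):
        res = risk_ratio(ContingencyTable2x2(10, 10, 20, 20))
        assert res.rr == pytest.approx(1.0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_zero_numerator_cell_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            risk_ratio(ContingencyTable2x2(0, 10, 5, 5))

    def test_negative_count_rejected(self):
        with pytest.raises(DomainError):
            ContingencyTable2x2(-1, 2, 3, 4)


def brute_force_fisher(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisherExact:
    def test_pd_row_two_decimals(self):
        p = fisher_exact(ContingencyTable2x2(7, 25, 25, 26))
        assert round(p, 2) == 0.02

    def test_symmetric_table_p_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "table", [(10, 0, 0, 10), (7, 25, 25, 26), (3, 9, 6, 2), (1, 1, 9, 9)]
    )
    def test_matches_enumeration_oracle(self, table):
        p = fisher_exact(ContingencyTable2x2(*table))
        assert p == pytest.approx(brute_force_fisher(*table), rel=1e-9)

    def test_transposition_invariance(self):
        a, b, c, d = 7, 25, 25, 26
        p_rows = fisher_exact(ContingencyTable2x2(a, b, c, d))
        p_cols = fisher_exact(ContingencyTable2x2(a, c, b, d))
        assert p_rows == pytest.approx(p_cols)


class TestKaplanMeier:
    def test_uncensored_median(self):
        fit = km_fit([1, 2, 3, 4, 5], [1, 1, 1, 1, 1])
        assert fit.median == pytest.approx(3.0)

    def test_all_censored_not_reached(self):
        fit = km_fit([4, 5, 6], [0, 0, 0])
        assert fit.median is None
        assert fit.median_followup == pytest.approx(5.0)

    def test_hand_computed_product_limit_table(self):
        # 8 patients: events at 1,3,4,5,7; censored at 2,4,6
        times = [1, 2, 3, 4, 4, 5, 6, 7]
        events = [1, 0, 1, 1, 0, 1, 0, 1]
        fit = km_fit(times, events)
        s = fit.survival.set_index("time")["survival"]
        assert s.loc[1] == pytest.approx(7 / 8)
        assert s.loc[3] == pytest.approx(7 / 8 * 5 / 6)
        assert s.loc[4] == pytest.approx(7 / 8 * 5 / 6 * 4 / 5)
        assert s.loc[5] == pytest.approx(7 / 8 * 5 / 6 * 4 / 5 * 2 / 3)
        assert s.loc[7] == pytest.approx(0.0)
        assert fit.median == pytest.approx(5.0)

    def test_reduces_to_empirical_survival_without_censoring(self, rng):
        times = rng.exponential(5.0, 40).round(2)
        fit = km_fit(times, np.ones_like(times))
        for t, s in zip(fit.survival["time"], fit.survival["survival"]):
            assert s == pytest.approx((times > t).mean())

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyInputError):
            km_fit([], [])


def manual_two_group_logrank(t1, e1, t2, e2):
    """Observed-minus-expected log-rank chi-square (independent oracle)."""
    t1, e1, t2, e2 = map(np.asarray, (t1, e1, t2, e2))
    event_times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o_minus_e, var = 0.0, 0.0
    for t in event_times:
        n1, n2 = (t1 >= t).sum(), (t2 >= t).sum()
        d1, d2 = ((t1 == t) & (e1 == 1)).sum(), ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogRank:
    def test_identical_groups_null(self):
        times, events = [1, 2, 3, 4, 5], [1, 1, 0, 1, 1]
        res = log_rank([(times, events), (times, events)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_group_matches_manual_computation(self, rng):
        t1 = rng.exponential(4.0, 25).round(1) + 0.1
        t2 = rng.exponential(9.0, 25).round(1) + 0.1
        e1 = rng.random(25) < 0.8
        e2 = rng.random(25) < 0.8
        res = log_rank([(t1, e1.astype(int)), (t2, e2.astype(int))],
                       with_hazard_ratio=False)
        expected = manual_two_group_logrank(t1, e1.astype(int), t2, e2.astype(int))
        assert res.statistic == pytest.approx(expected, rel=1e-6)

    def test_four_group_comparison_supported(self, rng):
        groups = [
            (rng.exponential(m, 20), np.ones(20)) for m in (3.0, 5.0, 8.0, 20.0)
        ]
        res = log_rank(groups)
        assert res.degrees_of_freedom == 3
        assert 0 <= res.p_value <= 1

    def test_single_group_rejected(self):
        with pytest.raises(ArityError):
            log_rank([([1, 2], [1, 1])])

    def test_hazard_ratio_direction(self, rng):
        fast = (rng.exponential(2.0, 40), np.ones(40))
        slow = (rng.exponential(20.0, 40), np.ones(40))
        res = log_rank([fast, slow])
        assert res.hazard_ratio > 1  # first group has the higher hazard
        assert res.hr_ci_low <= res.hazard_ratio <= res.hr_ci_high


class TestCoxPh:
    def _two_group_frame(self, rng, medians=(3.0, 12.0), n=60):
        group = np.repeat([1, 0], n)
        latent = rng.exponential(np.where(group == 1, *medians), 2 * n)
        censor = rng.uniform(5, 30, 2 * n)
        return pd.DataFrame(
            {
                "time": np.minimum(latent, censor),
                "event": (latent <= censor).astype(int),
                "group": group,
            }
        )

    def test_direction_consistent_with_log_rank(self, rng):
        df = self._two_group_frame(rng)
        res = cox_ph(df, "time", "event", ["group"])
        g1 = df[df.group == 1]
        g0 = df[df.group == 0]
        lr = log_rank([(g1.time, g1.event), (g0.time, g0.event)])
        assert (res.hazard_ratio("group") > 1) == (lr.hazard_ratio > 1)
        assert res.hazard_ratio("group") > 1

    def test_null_covariate_gives_unit_hazard(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0]
        events = [1, 1, 0, 1, 1, 0, 1, 1]
        df = pd.DataFrame(
            {
                "time": times * 2,
                "event": events * 2,
                "group": [0] * 8 + [1] * 8,
            }
        )
        res = cox_ph(df, "time", "event", ["group"])
        assert res.hazard_ratio("group") == pytest.approx(1.0, abs=1e-6)

    def test_single_stratum_equals_unstratified(self, rng):
        df = self._two_group_frame(rng)
        df["stratum"] = "only"
        plain = cox_ph(df, "time", "event", ["group"])
        strat = cox_ph(df, "time", "event", ["group"], strata="stratum")
        assert strat.summary.loc["group", "coef"] == pytest.approx(
            plain.summary.loc["group", "coef"], rel=1e-6
        )

    def test_no_events_degenerate(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0], "x": [0, 1, 0]})
        with pytest.raises(DegenerateModelError):
            cox_ph(df, "time", "event", ["x"])


class TestBackwardAicLogistic:
    def _informative_noise_data(self, rng, n=400):
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)  # pure noise
        p = 1 / (1 + np.exp(-(-0.3 + 1.3 * x1)))
        y = (rng.random(n) < p).astype(int)
        return y, pd.DataFrame({"x1": x1, "x2": x2})

    def test_noise_term_removed_matches_exhaustive_aic(self, rng):
        import statsmodels.api as sm

        y, X = self._informative_noise_data(rng)
        res = backward_aic_logistic(y, X)
        # exhaustive oracle over all 4 subsets
        aics = {}
        for subset in [(), ("x1",), ("x2",), ("x1", "x2")]:
            design = sm.add_constant(X[list(subset)], has_constant="add")
            aics[subset] = sm.Logit(y, design).fit(disp=0).aic
        assert min(aics, key=aics.get) == ("x1",)
        assert res.retained == ["x1"]
        trace_values = [a for _, a in res.aic_trace]
        assert trace_values == sorted(trace_values, reverse=True)

    def test_fixed_point_when_every_removal_hurts(self, rng):
        n = 400
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        p = 1 / (1 + np.exp(-(1.5 * x1 - 1.5 * x2)))
        y = (rng.random(n) < p).astype(int)
        res = backward_aic_logistic(y, pd.DataFrame({"x1": x1, "x2": x2}))
        assert sorted(res.retained) == ["x1", "x2"]

    def test_empty_candidates_intercept_only(self, rng):
        y = np.r_[np.ones(20), np.zeros(20)]
        res = backward_aic_logistic(y, pd.DataFrame(index=range(40)))
        assert res.retained == []
        assert np.isfinite(res.aic_trace[0][1])

    def test_forced_terms_recorded_and_auroc_improves(self, rng):
        n = 600
        conf = rng.normal(size=n)
        tmb = rng.normal(size=n)
        phbr = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(0.5 * conf + 0.9 * tmb + 0.9 * phbr)))
        y = (rng.random(n) < p).astype(int)
        X = pd.DataFrame({"conf": conf})
        forced = pd.DataFrame({"tmb": tmb, "phbr": phbr})
        res = backward_aic_logistic(y, X, forced_terms=forced)
        assert set(res.forced_aic) == {"tmb", "phbr"}
        # both effects active: combined model separates at least as well as
        # either single added score
        both = res.forced_auroc["phbr"]
        assert both >= auroc(tmb, y) - 0.02
        assert both >= auroc(phbr, y) - 0.02

    def test_non_binary_outcome_rejected(self, rng):
        with pytest.raises(DomainError):
            backward_aic_logistic([0, 1, 2], pd.DataFrame({"x": [1, 2, 3]}))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_matches_pair_counting(self):
        scores = [0.2, 0.6, 0.4, 0.9]
        labels = [0, 1, 0, 1]
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        assert auroc(scores, labels) == pytest.approx(np.mean(pairs))

    def test_independent_scores_near_half(self, rng):
        scores = rng.random(4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(auroc(scores, labels) - 0.5) < 0.03

    def test_one_class_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            auroc([0.1, 0.2], [1, 1])


class TestSpearman:
    def test_monotone_extremes(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, [2, 4, 8, 16, 32])[0] == pytest.approx(1.0)
        assert spearman(x, [32, 16, 8, 4, 2])[0] == pytest.approx(-1.0)

    def test_tie_handled_by_midranks(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0]  # midranks: 1, 2.5, 2.5, 4, 5
        y = [10.0, 20.0, 30.0, 40.0, 50.0]
        rx = np.array([1, 2.5, 2.5, 4, 5])
        ry = np.array([1, 2, 3, 4, 5])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedEstimateError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestMannWhitney:
    def test_identical_samples(self):
        _, p = mann_whitney([1, 2, 3, 4], [1, 2, 3, 4])
        assert p > 0.9

    def test_complete_separation_u_extreme(self):
        u, _ = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u in (0.0, 9.0)

    def test_exact_p_matches_permutation_enumeration(self):
        x = [1.2, 3.4, 2.2]
        y = [0.5, 4.1, 6.0, 2.9]
        u_obs, p = mann_whitney(x, y)
        pooled = x + y
        us = []
        for idx in itertools.combinations(range(len(pooled)), len(x)):
            xs = [pooled[i] for i in idx]
            ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
            us.append(sum(1.0 for a in xs for b in ys if a > b))
        us = np.array(us)
        p_enum = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
        assert p == pytest.approx(p_enum)

    def test_empty_sample_rejected(self):
        with pytest.raises(EmptyInputError):
            mann_whitney([], [1.0])
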