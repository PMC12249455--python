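"""Median split, log-rank, Cox models, Kaplan-Meier, survival screen."""

import numpy as np
import pandas as pd
import pytest

from bimodalsurv import (
    km_curve,
    logrank_test,
    median_dichotomize,
    multivariate_cox,
    screen_genes,
    simulate_survival,
    survival_screen,
    univariate_cox,
)


class TestMedianDichotomize:
    def test_even_split(self):
        assert list(median_dichotomize([1, 2, 3, 4])) == [0, 0, 1, 1]

    def test_ties_at_median_go_low(self):
        assert list(median_dichotomize([1, 2, 2, 3])) == [0, 0, 0, 1]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            median_dichotomize([5, 5, 5, 5])
        with pytest.raises(ValueError):
            median_dichotomize([1, 2, 3])

    def test_group_imbalance_bounded_by_median_ties(self, rng):
        v = rng.normal(size=111)
        lab = median_dichotomize(v)
        n_tied = int(np.sum(v == np.median(v)))
        assert abs((lab == 1).sum() - (lab == 0).sum()) <= n_tied


class TestLogrank:
    def test_identical_groups_null(self):
        t = np.r_[np.arange(1, 21), np.arange(1, 21)].astype(float)
        e = np.ones(40, int)
        lab = np.r_[np.zeros(20, int), np.ones(20, int)]
        stat, p = logrank_test(lab, t, e)
        assert stat == pytest.approx(0.0, abs=1e-8)
        assert p > 0.99

    def test_strong_effect_detected(self, rng):
        lab = (rng.random(5000) < 0.5).astype(int)
        t, e = simulate_survival(lab, 0.02, np.log(3), 0.3, rng)
        _, p = logrank_test(lab, t, e)
        assert p < 1e-10

    def test_agrees_with_cox_score_structure(self, rng):
        # for a binary covariate, log-rank and Cox give matching inference
        lab = (rng.random(200) < 0.5).astype(int)
        t = rng.exponential(50, 200)  # untied continuous times
        e = np.ones(200, int)
        _, p_lr = logrank_test(lab, t, e)
        res = univariate_cox(lab, t, e)
        assert np.isclose(p_lr, res["p_wald"], atol=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(np.zeros(10, int), np.arange(1, 11), np.ones(10, int))


class TestUnivariateCox:
    def test_null_covers_one(self, rng):
        lab = (rng.random(400) < 0.5).astype(int)
        t, e = simulate_survival(lab, 0.02, 0.0, 0.3, rng)
        res = univariate_cox(lab, t, e)
        assert res["estimable"]
        assert res["ci_low"] <= 1.0 <= res["ci_high"]
        assert 0.4 <= res["concordance"] <= 0.6

    def test_direction_contract(self, rng):
        lab = (rng.random(600) < 0.5).astype(int)
        t, e = simulate_survival(lab, 0.02, np.log(3), 0.2, rng)
        assert univariate_cox(lab, t, e)["direction"] == "poor"
        t2, e2 = simulate_survival(lab, 0.02, -np.log(3), 0.2, rng)
        assert univariate_cox(lab, t2, e2)["direction"] == "good"

    def test_no_events_flagged_not_raised(self):
        lab = np.r_[np.zeros(5, int), np.ones(5, int)]
        res = univariate_cox(lab, np.arange(1.0, 11.0), np.zeros(10, int))
        assert res["estimable"] is False
        assert np.isnan(res["hr"])

    def test_permutation_symmetry_of_log_hr(self, rng):
        # permuted labels: log HR symmetric about 0
        t, e = simulate_survival(np.zeros(100, int), 0.02, 0.0, 0.3, rng)
        log_hrs = []
        for _ in range(60):
            lab = rng.permutation(np.r_[np.zeros(50, int), np.ones(50, int)])
            r = univariate_cox(lab, t, e)
            if r["estimable"]:
                log_hrs.append(np.log(r["hr"]))
        assert abs(np.median(log_hrs)) < 0.25


class TestMultivariateCox:
    def test_adjusted_close_to_unadjusted_without_confounding(self, rng):
        lab = (rng.random(500) < 0.5).astype(int)
        t, e = simulate_survival(lab, 0.02, np.log(2.5), 0.3, rng)
        age = rng.normal(50, 10, 500)
        stage = rng.choice(["I", "II", "III", "IV"], 500)
        gender = rng.choice(["male", "female"], 500)
        uni = univariate_cox(lab, t, e)
        adj = multivariate_cox(lab, t, e, age, stage, gender)
        assert adj["estimable"]
        assert uni["ci_low"] <= adj["hr"] <= uni["ci_high"]
        assert set(adj["covariates"]) == {"group", "age", "stage_adv", "male"}

    def test_stage_mediation_attenuates_gene_effect(self, rng):
        # gene label and stage identical: adjusted gene HR falls toward 1
        lab = (rng.random(800) < 0.5).astype(int)
        t, e = simulate_survival(lab, 0.02, np.log(3), 0.2, rng)
        stage = np.where(lab == 1, "IV", "I")
        age = rng.normal(50, 10, 800)
        gender = rng.choice(["male", "female"], 800)
        uni = univariate_cox(lab, t, e)
        adj = multivariate_cox(lab, t, e, age, stage, gender)
        assert not adj["estimable"] or adj["hr"] < uni["hr"]

    def test_missing_stage_complete_case(self, rng):
        lab = (rng.random(200) < 0.5).astype(int)
        t, e = simulate_survival(lab, 0.02, np.log(2), 0.3, rng)
        stage = rng.choice(["I", "II", "III", "IV"], 200).astype(object)
        stage[:5] = None
        adj = multivariate_cox(lab, t, e, rng.normal(50, 10, 200), stage,
                               rng.choice(["male", "female"], 200))
        assert adj["n_high"] + adj["n_low"] == 195


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        lab = np.r_[np.zeros(4, int), np.ones(4, int)]
        km = km_curve(lab, np.arange(1.0, 9.0), np.zeros(8, int))
        assert (km["survival"] == 1.0).all()

    def test_distinct_event_times_drop_by_one_over_n(self):
        km = km_curve(np.r_[np.zeros(5, int), np.ones(2, int)],
                      np.r_[np.arange(1.0, 6.0), [9.0, 10.0]],
                      np.ones(7, int))
        low = km[km["group"] == "low"]
        surv = low.loc[low["time"] > 0, "survival"].to_numpy()
        assert surv == pytest.approx([0.8, 0.6, 0.4, 0.2, 0.0])

    def test_matches_hand_computed_product_limit(self):
        # classic worked example: times 6,6,6,7,10 with censoring at 6,9
        t = np.array([6, 6, 6, 6, 7, 9, 10.0])
        e = np.array([1, 1, 1, 0, 1, 0, 1])
        lab = np.zeros(7, int)
        km = km_curve(np.r_[lab, np.ones(2, int)],
                      np.r_[t, [5.0, 5.0]], np.r_[e, [1, 1]])
        low = km[km["group"] == "low"].set_index("time")["survival"]
        # S(6) = 1 - 3/7; S(7) = S(6) * (1 - 1/3); S(10) = S(7) * (1 - 1/1)
        assert low.loc[6.0] == pytest.approx(4 / 7)
        assert low.loc[7.0] == pytest.approx((4 / 7) * (2 / 3))
        assert low.loc[10.0] == pytest.approx(0.0)

    def test_row_order_invariance(self, rng):
        lab = (rng.random(50) < 0.5).astype(int)
        t, e = simulate_survival(lab, 0.02, np.log(2), 0.3, rng)
        km1 = km_curve(lab, t, e)
        perm = rng.permutation(50)
        km2 = km_curve(lab[perm], t[perm], e[perm])
        pd.testing.assert_frame_equal(km1, km2)


class TestSurvivalScreen:
    def test_counts_and_direction_partition(self, small_cohort):
        rec = screen_genes(small_cohort.expression, n_boot=300, rng=1)
        res, counts = survival_screen(rec, small_cohort.expression,
                                      small_cohort.clinical)
        assert counts["n_tested"] == int(rec["rank"].notna().sum())
        sig = res[res["significant"]]
        assert counts["n_significant"] == len(sig)
        assert counts["n_poor"] + counts["n_good"] == counts["n_significant"]
        assert (sig.loc[sig["direction"] == "poor", "hr"] > 1).all()
        assert counts["n_multivariate_robust"] <= counts["n_significant"]

    def test_sample_mismatch_rejected(self, small_cohort):
        rec = screen_genes(small_cohort.expression, n_boot=300, rng=1)
        bad_clin = small_cohort.clinical.copy()
        bad_clin.loc[0, "sample_id"] = "NOT_A_SAMPLE"
        with pytest.raises(ValueError, match="sample ids"):
            survival_screen(rec, small_cohort.expression, bad_clin)

    def test_planted_prognostic_genes_detected_as_poor(self, small_cohort):
        rec = screen_genes(small_cohort.expression, n_boot=300, rng=1)
        res, _ = survival_screen(rec, small_cohort.expression,
                                 small_cohort.clinical)
        planted = res["feature_id"].str.startswith("BIM")
        sig_planted = res[planted & res["significant"]]
        assert len(sig_planted) >= 0.7 * planted.sum()
        assert (sig_planted["direction"] == "poor").all()
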