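"""Survival screening, duplicates, meta-analysis and enrichment."""

import numpy as np
import pandas as pd
import pytest

from cnge import (
    auc,
    cox_multivariate,
    cox_univariate,
    detect_duplicates,
    dichotomize_two_year,
    enrichment_fisher,
    km_dichotomized,
    meta_random_effects,
)


def _clinical(times, events, **extra):
    df = pd.DataFrame(
        {
            "os_months": times,
            "event": events,
        },
        index=[f"s{i}" for i in range(len(times))],
    )
    for k, v in extra.items():
        df[k] = v
    return df


class TestTwoYearDichotomization:
    def test_rules(self):
        clin = _clinical([10.0, 30.0, 10.0], [1, 0, 0])
        outcome, n_excluded = dichotomize_two_year(clin)
        assert outcome.tolist()[:2] == ["short", "long"]
        assert pd.isna(outcome.iloc[2])
        assert n_excluded == 1

    def test_death_after_two_years_is_long(self):
        clin = _clinical([30.0], [1])
        outcome, _ = dichotomize_two_year(clin)
        assert outcome.iloc[0] == "long"


class TestAuc:
    def test_perfect_separation(self):
        out = pd.Series(["short", "short", "long", "long"])
        assert auc(np.array([3.0, 4.0, 1.0, 2.0]), out) == 1.0

    def test_enumerated_quarter(self):
        out = pd.Series(["short", "short", "long", "long"])
        assert auc(np.array([1.0, 3.0, 2.0, 4.0]), out) == 0.25

    def test_all_ties_give_half(self):
        out = pd.Series(["short", "long", "short", "long"])
        assert auc(np.ones(4), out) == 0.5

    def test_empty_class_not_estimable(self):
        assert np.isnan(auc(np.array([1.0, 2.0]), pd.Series(["short", "short"])))

    def test_rank_identity_equals_pairwise_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(4, 50))
            x = np.round(rng.normal(0, 1, n), 1)  # rounding induces ties
            out = pd.Series(np.where(rng.random(n) < 0.5, "short", "long"))
            if (out == "short").sum() == 0 or (out == "long").sum() == 0:
                continue
            xs = x[out == "short"]
            xl = x[out == "long"]
            brute = np.mean([
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in xs for b in xl
            ])
            assert auc(x, out) == pytest.approx(brute, abs=1e-12)


def _ph_cohort(rng, n, gamma, censor_months=60.0):
    x = rng.normal(0, 1, n)
    lam0 = np.log(2) / 30.0
    t = rng.exponential(1.0 / (lam0 * np.exp(gamma * x)))
    c = rng.uniform(0, censor_months, n)
    clin = _clinical(np.maximum(np.minimum(t, c), 1e-3), (t <= c).astype(int))
    return x, clin


class TestCox:
    def test_null_marker_estimates_near_zero(self):
        rng = np.random.default_rng(0)
        covered = 0
        for _ in range(30):
            x, clin = _ph_cohort(rng, 300, 0.0)
            res = cox_univariate(x, clin)
            covered += abs(res.log_hr) < 2 * res.se
        assert covered >= 26  # ~95% coverage with a small-sample band

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        estimates = []
        for _ in range(20):
            x, clin = _ph_cohort(rng, 1000, 0.5)
            estimates.append(cox_univariate(x, clin).log_hr)
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.15)

    def test_duplicated_data_same_estimate_smaller_se(self):
        rng = np.random.default_rng(2)
        x, clin = _ph_cohort(rng, 150, 0.4)
        res = cox_univariate(x, clin)
        clin2 = pd.concat([clin, clin]).reset_index(drop=True)
        clin2.index = [f"s{i}" for i in range(len(clin2))]
        res2 = cox_univariate(np.concatenate([x, x]), clin2)
        # replication duplicates every event time; Efron tie handling makes
        # the estimate agree only approximately (exact under Breslow)
        assert res2.log_hr == pytest.approx(res.log_hr, abs=0.01)
        assert res2.se < res.se

    def test_constant_marker_not_estimable(self):
        clin = _clinical([5.0, 10.0, 15.0], [1, 1, 1])
        assert not cox_univariate(np.ones(3), clin).estimable

    def test_empty_covariates_reduce_to_univariate(self):
        rng = np.random.default_rng(3)
        x, clin = _ph_cohort(rng, 200, 0.3)
        uni = cox_univariate(x, clin)
        multi = cox_multivariate(x, clin, covariates=())
        assert multi.log_hr == pytest.approx(uni.log_hr)

    def test_adjustment_leaves_independent_effect(self):
        rng = np.random.default_rng(4)
        x, clin = _ph_cohort(rng, 600, 0.4)
        clin["age"] = rng.normal(65, 8, len(clin))
        clin["stage"] = rng.choice([1, 2, 3], len(clin))
        clin["histology"] = rng.choice(["adeno", "squamous"], len(clin))
        uni = cox_univariate(x, clin)
        multi = cox_multivariate(x, clin)
        assert multi.log_hr == pytest.approx(uni.log_hr, abs=0.1)

    def test_collinear_covariate_dropped_not_fatal(self):
        rng = np.random.default_rng(5)
        x, clin = _ph_cohort(rng, 100, 0.4)
        clin["age"] = 50.0  # constant -> collinear with baseline
        res = cox_multivariate(x, clin, covariates=("age",))
        assert res.estimable


class TestKmDichotomized:
    def test_percentile_rule_group_sizes(self):
        rng = np.random.default_rng(0)
        x, clin = _ph_cohort(rng, 100, 0.0)
        res = km_dichotomized(x, clin, rule="percentile", q=0.75)
        assert res["n_high"] == 25 and res["n_low"] == 75

    def test_identical_groups_give_large_p(self):
        t = np.repeat([5.0, 10.0, 20.0, 40.0], 10)
        clin = _clinical(t, np.ones_like(t, dtype=int))
        x = np.tile([0.0, 1.0], 20)  # every survival time in both arms equally
        res = km_dichotomized(x, clin, rule="percentile", q=0.5)
        assert res["p"] > 0.9

    def test_optimized_never_beats_itself(self):
        rng = np.random.default_rng(1)
        for rep in range(5):
            x, clin = _ph_cohort(rng, 80, 0.3)
            p_opt = km_dichotomized(x, clin, rule="optimized")["p"]
            p_pct = km_dichotomized(x, clin, rule="percentile", q=0.75)["p"]
            assert p_opt <= p_pct + 1e-12

    def test_unknown_rule_rejected(self):
        clin = _clinical([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            km_dichotomized(np.array([1.0, 2.0]), clin, rule="median-ish")


class TestDuplicates:
    def test_identical_vectors_found(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame(rng.uniform(1, 10, (100, 3)), columns=["a0", "a1", "a2"])
        b = pd.DataFrame(rng.uniform(1, 10, (100, 2)), columns=["b0", "b1"])
        b["b1"] = a["a2"].to_numpy()
        dup = detect_duplicates({"A": a, "B": b})
        assert len(dup) == 1
        assert dup.iloc[0]["sample_a"] == "a2" and dup.iloc[0]["sample_b"] == "b1"
        assert dup.iloc[0]["remove_cohort"] == "B"

    def test_independent_vectors_not_flagged(self):
        rng = np.random.default_rng(1)
        a = pd.DataFrame(rng.uniform(1, 10, (2000, 20)))
        b = pd.DataFrame(rng.uniform(1, 10, (2000, 20)))
        assert len(detect_duplicates({"A": a, "B": b})) == 0

    def test_planted_duplicates_recovered_exactly(self):
        from conftest import mini_config
        from cnge import simulate_meta_cohorts

        cohorts = simulate_meta_cohorts(mini_config(duplicate_pairs=2))
        dup = detect_duplicates({c.name: c.expression for c in cohorts})
        got = {
            tuple(sorted([(r.cohort_a, r.sample_a), (r.cohort_b, r.sample_b)]))
            for r in dup.itertuples()
        }
        want = {
            tuple(sorted(map(tuple, pair)))
            for pair in cohorts[0].ground_truth.duplicate_pairs
        }
        assert got == want

    def test_zero_duplicates_config(self):
        from conftest import mini_config
        from cnge import simulate_meta_cohorts

        cohorts = simulate_meta_cohorts(mini_config(duplicate_pairs=0))
        assert len(detect_duplicates({c.name: c.expression for c in cohorts})) == 0


class TestMeta:
    def test_identical_studies_have_no_heterogeneity(self):
        res = meta_random_effects(np.full(5, 0.3), np.full(5, 0.1))
        assert res["pooled_log_hr"] == pytest.approx(0.3)
        assert res["Q"] == pytest.approx(0.0)
        assert res["tau2"] == 0.0

    def test_three_study_closed_form(self):
        # hand computation: w = 100 each; b_FE = 0.4; Q = 100(0.04+0+0.04) = 8;
        # denom = 300 - 30000/300 = 200; tau2 = 6/200 = 0.03; w* = 25 each;
        # pooled = 0.4; se = (75)^(-1/2)
        res = meta_random_effects(np.array([0.2, 0.4, 0.6]), np.array([0.1, 0.1, 0.1]))
        assert res["Q"] == pytest.approx(8.0, abs=1e-10)
        assert res["tau2"] == pytest.approx(0.03, abs=1e-10)
        assert res["pooled_log_hr"] == pytest.approx(0.4, abs=1e-10)
        assert res["pooled_se"] == pytest.approx(75 ** -0.5, abs=1e-10)
        assert res["ci95"][0] < 0.4 < res["ci95"][1]

    def test_agrees_with_statsmodels_dl(self):
        from statsmodels.stats.meta_analysis import combine_effects

        rng = np.random.default_rng(0)
        for _ in range(20):
            k = int(rng.integers(2, 12))
            b = rng.normal(0.2, 0.3, k)
            se = rng.uniform(0.05, 0.4, k)
            ours = meta_random_effects(b, se)
            ref = combine_effects(b, se**2, method_re="dl")
            # statsmodels reports (and weights by) the untruncated DL
            # estimate; standard DL truncates tau2 at zero, so compare the
            # pooled value only when no truncation occurred and check the
            # fixed-effect limit otherwise
            assert ours["tau2"] == pytest.approx(max(0.0, ref.tau2), abs=1e-10)
            frame = ref.summary_frame()
            if ref.tau2 > 0:
                assert ours["pooled_log_hr"] == pytest.approx(
                    frame.loc["random effect", "eff"], abs=1e-10
                )
            else:
                assert ours["pooled_log_hr"] == pytest.approx(
                    frame.loc["fixed effect", "eff"], abs=1e-10
                )

    def test_fixed_effect_limit_when_tau_zero(self):
        b = np.array([0.30, 0.31, 0.29, 0.305])
        se = np.array([0.2, 0.25, 0.22, 0.21])
        res = meta_random_effects(b, se)
        assert res["tau2"] == 0.0
        w = 1 / se**2
        assert res["pooled_log_hr"] == pytest.approx(float((w * b).sum() / w.sum()))
        assert res["pooled_se"] <= se.min()

    def test_single_study_not_estimable(self):
        assert not meta_random_effects(np.array([0.3]), np.array([0.1]))["estimable"]

    def test_cohort_level_recovery(self):
        # per-study true effects vary around 0.3 with sd 0.1
        rng = np.random.default_rng(2)
        pooled = []
        for _ in range(10):
            betas, ses = [], []
            for _ in range(10):
                gamma = rng.normal(0.3, 0.1)
                x, clin = _ph_cohort(rng, 150, gamma)
                res = cox_univariate(x, clin)
                betas.append(res.log_hr)
                ses.append(res.se)
            pooled.append(meta_random_effects(np.array(betas), np.array(ses))["pooled_log_hr"])
        assert np.mean(pooled) == pytest.approx(0.3, abs=0.1)


class TestEnrichment:
    def test_tail_of_constructed_table(self):
        idx = [f"p{i}" for i in range(100)]
        hc = pd.Series([True] * 10 + [False] * 90, index=idx)
        pr = pd.Series([True] * 8 + [False] * 2 + [True] * 2 + [False] * 88, index=idx)
        res = enrichment_fisher(hc, pr)
        assert res["a"] == 8 and res["b"] == 2 and res["c"] == 2 and res["d"] == 88
        from scipy.stats import hypergeom

        want = hypergeom.sf(7, 100, 10, 10)
        assert res["p_one_sided"] == pytest.approx(want, rel=1e-12)

    def test_extreme_table_is_point_mass(self):
        idx = [f"p{i}" for i in range(50)]
        hc = pd.Series([True] * 5 + [False] * 45, index=idx)
        pr = hc.copy()
        res = enrichment_fisher(hc, pr)
        from scipy.stats import hypergeom

        assert res["p_one_sided"] == pytest.approx(hypergeom.pmf(5, 50, 5, 5), rel=1e-9)

    def test_degenerate_margin_warns_p_one(self):
        idx = [f"p{i}" for i in range(10)]
        hc = pd.Series([True] * 10, index=idx)
        pr = pd.Series([True] * 5 + [False] * 5, index=idx)
        with pytest.warns(UserWarning):
            res = enrichment_fisher(hc, pr)
        assert res["p_one_sided"] == 1.0

    def test_transpose_invariance(self):
        rng = np.random.default_rng(0)
        idx = [f"p{i}" for i in range(200)]
        hc = pd.Series(rng.random(200) < 0.2, index=idx)
        pr = pd.Series(rng.random(200) < 0.3, index=idx)
        assert enrichment_fisher(hc, pr)["p_one_sided"] == pytest.approx(
            enrichment_fisher(pr, hc)["p_one_sided"], rel=1e-12
        )

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(200):
            idx = range(300)
            hc = pd.Series(rng.random(300) < 0.1, index=idx)
            pr = pd.Series(rng.random(300) < 0.2, index=idx)
            if hc.any() and not hc.all() and pr.any() and not pr.all():
                ps.append(enrichment_fisher(hc, pr)["p_one_sided"])
        # one-sided discrete p-values are stochastically >= uniform
        assert np.mean(np.array(ps) < 0.05) < 0.1
        assert np.median(ps) > 0.25
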