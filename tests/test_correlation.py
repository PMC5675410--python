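"""The ECCC statistic, its significance test, and the downstream analyses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cnge import (
    CenteringSpec,
    compare_gene_set,
    eccc,
    eccc_table,
    equally_directed_test,
    flag_loss_candidates,
    permutation_null,
    quantile_class_analysis,
)
from cnge.correlation import equally_directed_scores
from cnge.integration import PairedData


def fixed_center_correlation(ge, cn, cy, cx):
    """Independent brute-force oracle: correlation with prescribed centers."""
    dx = [v - cx for v in cn]
    dy = [v - cy for v in ge]
    num = sum(a * b for a, b in zip(dx, dy))
    den = (sum(a * a for a in dx) * sum(b * b for b in dy)) ** 0.5
    return num / den


class TestEccc:
    def test_proportional_deviations_give_one(self):
        assert eccc([1, 1, 1, 5], [2, 2, 2, 6]) == pytest.approx(1.0)

    def test_anti_proportional_give_minus_one(self):
        spec = CenteringSpec(ge_center_rule="fixed_value", ge_center_value=5.0)
        assert eccc([5, 5, 5, 1], [2, 2, 2, 6], spec) == pytest.approx(-1.0)

    def test_hand_checked_example(self):
        ge = [0.9, 1.0, 1.2, 3.5]
        cn = [1.8, 2.0, 2.2, 4.0]
        want = fixed_center_correlation(ge, cn, cy=1.1, cx=2.0)
        assert want == pytest.approx(0.997, abs=5e-4)
        assert eccc(ge, cn) == pytest.approx(want, abs=1e-12)

    def test_degenerate_deviations_flagged_nan(self):
        assert np.isnan(eccc([1.0, 1.0, 1.0], [2.0, 2.0, 2.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            eccc([1.0, 2.0, 3.0], [2.0, 2.0])

    def test_equals_pearson_when_centered_at_means(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(4, 40)
            ge = rng.uniform(1, 10, n)
            cn = rng.uniform(0.5, 8, n)
            spec = CenteringSpec(
                cn_center=cn.mean(), ge_center_rule="fixed_value",
                ge_center_value=ge.mean(),
            )
            assert eccc(ge, cn, spec) == pytest.approx(
                np.corrcoef(ge, cn)[0, 1], abs=1e-12
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 50)
        val = eccc(rng.uniform(0.1, 20, n), rng.uniform(0.1, 10, n))
        assert np.isnan(val) or -1.0 <= val <= 1.0

    def test_invariant_to_joint_positive_rescaling(self):
        rng = np.random.default_rng(1)
        ge = rng.uniform(1, 10, 20)
        cn = rng.uniform(0.5, 8, 20)
        base = eccc(ge, cn, CenteringSpec(cn_center=2.0))
        scaled = eccc(ge, cn * 3.0, CenteringSpec(cn_center=6.0))
        assert scaled == pytest.approx(base, abs=1e-12)


class TestEquallyDirectedTest:
    def test_all_at_centers_gives_p_one(self):
        assert equally_directed_test([5.0] * 6, [2.0] * 6) == 1.0

    def test_three_positive_scores_exact_eighth(self):
        # 2^3 equally likely sign assignments; only the all-positive one has
        # a rank sum as large -> p = 1/8
        ge = [1.0, 1.0, 1.0, 2.0, 3.0, 4.0]
        cn = [2.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        assert equally_directed_test(ge, cn) == pytest.approx(0.125)

    def test_focal_constellation_scores_and_p(self):
        ge = np.array([0.9, 1.0, 1.2, 3.5])
        cn = np.array([1.8, 2.0, 2.2, 4.0])
        scores = equally_directed_scores(ge, cn)
        assert scores == pytest.approx([0.2, 0.0, 0.1, 2.0])
        assert equally_directed_test(ge, cn) == pytest.approx(0.125)

    def test_near_center_cn_counts_as_zero(self):
        spec = CenteringSpec(cn_zero_tolerance=0.05)
        scores = equally_directed_scores(
            np.array([1.0, 5.0]), np.array([2.01, 1.99]), spec
        )
        assert scores == pytest.approx([0.0, 0.0])


def _paired_from(expr, cn, genes=None, chrom="1"):
    idx = [f"p{i}" for i in range(expr.shape[0])]
    cols = [f"s{i}" for i in range(expr.shape[1])]
    ann = pd.DataFrame(
        {
            "gene": genes if genes is not None else [f"G{i}" for i in range(len(idx))],
            "chromosome": chrom,
            "start": 1,
            "stop": 100,
            "position": np.arange(len(idx)) * 1000 + 500,
        },
        index=idx,
    )
    e = pd.DataFrame(expr, index=idx, columns=cols)
    c = pd.DataFrame(cn, index=idx, columns=cols)
    calls = pd.DataFrame(np.where(c > 4.0, 2, 0), index=idx, columns=cols)
    return PairedData(annotation=ann, expression=e, cn=c, calls=calls)


class TestEcccTable:
    def test_single_probeset_fdr_equals_p(self):
        paired = _paired_from(
            np.array([[1.0, 1.0, 2.0, 5.0]]), np.array([[2.0, 2.0, 3.0, 6.0]])
        )
        table = eccc_table(paired)
        assert table["fdr_q"].iloc[0] == pytest.approx(table["p_value"].iloc[0])

    def test_sample_order_permutation_invariance(self, paired):
        table = eccc_table(paired)
        perm = np.random.default_rng(0).permutation(paired.expression.shape[1])
        shuffled = PairedData(
            annotation=paired.annotation,
            expression=paired.expression.iloc[:, perm],
            cn=paired.cn.iloc[:, perm],
            calls=paired.calls.iloc[:, perm],
        )
        table2 = eccc_table(shuffled)
        assert np.allclose(table["eccc"], table2["eccc"], equal_nan=True)

    def test_dosage_genes_flagged_on_synthetic_cohort(self, cohort, records):
        dosage = set(cohort.ground_truth.dosage_genes)
        flags = records["high_correlation"]
        sens = flags[flags.index.isin(dosage)].mean()
        fpr = flags[~flags.index.isin(dosage)].mean()
        assert sens >= 0.9
        assert fpr <= 0.01

    def test_fdr_q_at_least_p_and_monotone(self, records):
        assert (records["fdr_q"] >= records["p_value"] - 1e-15).all()
        srt = records.sort_values("p_value")
        assert (np.diff(srt["fdr_q"]) >= -1e-12).all()

    def test_high_implies_moderate(self, records):
        assert (
            records.loc[records["high_correlation"], "moderate_correlation"]
        ).all()


class TestPermutationNull:
    def test_centered_and_seeded(self, paired):
        # the desk-scale fixture is small; the default-scale cohort centers
        # more tightly (the skew of linear expression values is positive)
        null = permutation_null(paired, n_perm=20, seed=5)
        assert abs(null["mean"]) < 0.05
        again = permutation_null(paired, n_perm=20, seed=5)
        assert np.array_equal(null["null_values"], again["null_values"])

    def test_dosage_eccc_exceeds_null_tail(self, cohort, paired, records):
        null = permutation_null(paired, n_perm=20, seed=0)
        q999 = null["quantiles"]["q0.999"]
        dosage = [p for p in cohort.ground_truth.dosage_genes if p in records.index]
        assert (records.loc[dosage, "eccc"] > q999).mean() > 0.95

    def test_rejects_zero_perms(self, paired):
        with pytest.raises(ValueError):
            permutation_null(paired, n_perm=0)


class TestLossCandidates:
    @pytest.mark.parametrize(
        "median_cn,cn_q25,expected",
        [(1.8, 1.4, True), (1.8, 1.6, False), (2.0, 1.2, False)],
    )
    def test_rule(self, median_cn, cn_q25, expected):
        table = pd.DataFrame({"median_cn": [median_cn], "cn_q25": [cn_q25]})
        assert flag_loss_candidates(table)["loss_candidate"].iloc[0] is np.bool_(expected)

    def test_synthetic_loss_region_flagged(self, cohort, records):
        in_loss = (
            (records["chromosome"] == "3")
            & (records["position"] > 5_000_000)
            & (records["position"] <= 15_000_000)
        )
        assert records.loc[in_loss, "loss_candidate"].mean() > 0.9
        assert records.loc[~in_loss, "loss_candidate"].mean() < 0.05


class TestQuantileClasses:
    def test_fourteen_probesets_split_into_seven_pairs(self):
        rng = np.random.default_rng(0)
        paired = _paired_from(rng.uniform(1, 10, (14, 6)), rng.uniform(1, 4, (14, 6)))
        table = eccc_table(paired)
        report = quantile_class_analysis(table, "median_ge")
        assert [c["n"] for c in report["classes"]] == [2] * 7
        assert len(report["comparisons"]) == 6

    def test_identical_eccc_gives_p_one(self):
        table = pd.DataFrame(
            {
                "eccc": np.full(21, 0.5),
                "median_ge": np.arange(21, dtype=float),
                "median_cn": np.ones(21),
            }
        )
        report = quantile_class_analysis(table, "median_ge")
        assert all(c["p"] == pytest.approx(1.0) for c in report["comparisons"])

    def test_config_validation(self, records):
        with pytest.raises(ValueError):
            quantile_class_analysis(records, "median_ge", n_classes=1)
        with pytest.raises(ValueError):
            quantile_class_analysis(records, "something_else")

    def test_synthetic_gradient_detected(self):
        # ECCC rises with median expression by construction: high-expression
        # probe sets get proportionally less noise
        rng = np.random.default_rng(1)
        n_ps, n_s = 210, 60
        level = np.linspace(1, 10, n_ps)
        cn = np.full((n_ps, n_s), 2.0)
        carriers = rng.random((n_ps, n_s)) < 0.2
        cn[carriers] = 6.0
        noise_sd = 4.0 / level  # noisier at low expression
        ge = level[:, None] + 1.0 * (cn - 2.0) + rng.normal(0, 1, (n_ps, n_s)) * noise_sd[:, None]
        paired = _paired_from(np.maximum(ge, 0.05), cn)
        table = eccc_table(paired)
        report = quantile_class_analysis(table, "median_ge")
        medians = [c["eccc_median"] for c in report["classes"]]
        assert medians[-1] > medians[0]
        assert np.sum(np.diff(medians) > 0) >= 4


class TestGeneSetComparison:
    def test_no_difference_detected_as_null(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(400)],
                "eccc": rng.uniform(-0.2, 0.6, 400),
                "cn_p95": rng.uniform(2, 3, 400),
                "ge_p95": rng.uniform(5, 10, 400),
            }
        )
        res = compare_gene_set(table, {f"G{i}" for i in range(0, 400, 4)})
        assert res["p_unadjusted"] > 0.01
        assert abs(res["adjusted_coefficient"]) < 0.1

    def test_direct_shift_recovered_by_adjustment(self):
        rng = np.random.default_rng(1)
        n = 600
        in_set = np.arange(n) < 150
        cn_p95 = rng.uniform(2, 4, n)
        ge_p95 = rng.uniform(4, 12, n)
        ecccs = 0.1 * cn_p95 + 0.02 * ge_p95 + 0.3 * in_set + rng.normal(0, 0.05, n)
        table = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n)],
                "eccc": ecccs,
                "cn_p95": cn_p95,
                "ge_p95": ge_p95,
            }
        )
        res = compare_gene_set(table, {f"G{i}" for i in range(150)})
        assert res["adjusted_coefficient"] == pytest.approx(0.3, abs=0.03)

    def test_confounded_shift_vanishes_after_adjustment(self):
        # the in-set difference is carried entirely by higher CN levels
        rng = np.random.default_rng(2)
        n = 600
        in_set = np.arange(n) < 150
        cn_p95 = np.where(in_set, rng.uniform(3.5, 5, n), rng.uniform(2, 3.5, n))
        ge_p95 = rng.uniform(4, 12, n)
        ecccs = 0.2 * cn_p95 + rng.normal(0, 0.05, n)
        table = pd.DataFrame(
            {
                "gene": [f"G{i}" for i in range(n)],
                "eccc": ecccs,
                "cn_p95": cn_p95,
                "ge_p95": ge_p95,
            }
        )
        res = compare_gene_set(table, {f"G{i}" for i in range(150)})
        assert res["p_unadjusted"] < 1e-6
        assert abs(res["adjusted_coefficient"]) < 0.05

    def test_empty_intersection_rejected(self, records):
        with pytest.raises(ValueError):
            compare_gene_set(records, {"NOT_A_GENE"})
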