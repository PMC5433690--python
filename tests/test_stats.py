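"""Contingency tests, t tests, correlation, multiple-comparison rule and
the clinical-features summary."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from lpdscore import (
    SummaryStats,
    anova_lsd,
    chi2_test,
    fisher_exact_test,
    pairwise_with_correction,
    pearson_correlation,
    summarize_cohort,
    t_test_from_raw,
    t_test_from_summary,
)
from lpdscore.stats import ContingencyTable, fisher_two_sided_p, format_p


def enumeration_fisher_p(table) -> float:
    """Brute-force oracle: enumerate every 2x2 table with the observed
    margins, compute each probability from binomial coefficients, and sum
    those no larger than the observed table's."""
    (a, b), (c, d) = np.asarray(table)
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = []
    for k in range(lo, hi + 1):
        probs.append(math.comb(r1, k) * math.comb(n - r1, c1 - k) / math.comb(n, c1))
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


class TestChi2:
    def test_sex_2x2_reproduces_printed_p(self):
        r = chi2_test([[28, 26], [9, 34]])
        assert round(r.p_value, 3) == 0.002
        assert r.df == 1

    def test_laterality_3x2_reproduces_printed_p(self):
        r = chi2_test([[22, 32], [4, 24], [5, 38]])
        assert round(r.p_value, 3) == 0.001
        assert r.df == 2

    def test_proportional_table_is_independent(self):
        r = chi2_test([[10, 10], [20, 20]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_zero_margin_suggests_fisher(self):
        with pytest.raises(ValueError, match="[Ff]isher"):
            chi2_test([[0, 0], [5, 7]])

    def test_yates_correction_flag(self):
        plain = chi2_test([[28, 26], [9, 34]])
        yates = chi2_test([[28, 26], [9, 34]], continuity_correction=True)
        assert yates.p_value > plain.p_value
        assert round(yates.p_value, 3) != 0.002


class TestFisherExact:
    @pytest.mark.parametrize(
        "table", [[[1, 53], [1, 27]], [[1, 53], [1, 42]], [[1, 27], [1, 42]]]
    )
    def test_pain_rows_give_p_one(self, table):
        assert fisher_exact_test(table).p_value == pytest.approx(1.0)

    def test_symmetric_table(self):
        assert fisher_exact_test([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)

    def test_extreme_table_attains_enumeration_minimum(self):
        table = [[0, 10], [10, 0]]
        assert fisher_exact_test(table).p_value == pytest.approx(
            enumeration_fisher_p(table)
        )

    def test_non_2x2_rejected(self):
        with pytest.raises(ValueError, match="2x2"):
            fisher_exact_test([[1, 2], [3, 4], [5, 6]])

    def test_matches_scipy_on_random_tables(self):
        """Cross-check against the independent scipy implementation."""
        rng = np.random.default_rng(11)
        for _ in range(400):
            t = rng.integers(0, 25, size=(2, 2))
            ours = fisher_exact_test(t).p_value
            assert ours == pytest.approx(sps.fisher_exact(t)[1], abs=1e-12)

    def test_matches_enumeration_oracle_small_tables(self):
        """Exhaustive check against the margin-enumeration oracle, N <= 25."""
        for n in range(1, 26):
            for r1 in range(n + 1):
                for c1 in range(n + 1):
                    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
                    for a in range(lo, hi + 1):
                        t = [[a, r1 - a], [c1 - a, n - r1 - c1 + a]]
                        assert fisher_two_sided_p(*np.ravel(t)) == pytest.approx(
                            enumeration_fisher_p(t), abs=1e-10
                        )


class TestPermutationInvariance:
    def test_chi2_and_fisher_invariant_under_table_permutations(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            t = rng.integers(1, 20, size=(2, 2))
            base_chi = chi2_test(t).p_value
            base_fis = fisher_exact_test(t).p_value
            for perm in (t[::-1], t[:, ::-1], t.T, t[::-1, ::-1]):
                assert chi2_test(perm).p_value == pytest.approx(base_chi)
                assert fisher_exact_test(perm).p_value == pytest.approx(base_fis, abs=1e-12)

    def test_chi2_row_permutation_3x2(self):
        t = np.array([[22, 32], [4, 24], [5, 38]])
        base = chi2_test(t).p_value
        for perm in itertools.permutations(range(3)):
            assert chi2_test(t[list(perm)]).p_value == pytest.approx(base)


class TestTTests:
    def test_age_summary_reproduces_printed_significance(self):
        rfh = SummaryStats(54, 55.92, 12.85)
        malt = SummaryStats(43, 64.95, 12.16)
        r = t_test_from_summary(rfh, malt, variant="student")
        assert r.p_value < 0.001
        assert r.df == 95

    def test_identical_summaries_give_p_one(self):
        s = SummaryStats(20, 10.0, 2.0)
        r = t_test_from_summary(s, s)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_degenerate_zero_variance_rejected(self):
        s = SummaryStats(5, 1.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            t_test_from_summary(s, s)

    def test_identical_raw_samples_give_p_one(self):
        r = t_test_from_raw([1, 2, 3], [1, 2, 3])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_raw_path_equals_summary_path(self, variant):
        """The two independent code paths agree to 10 significant digits."""
        rng = np.random.default_rng(23)
        for _ in range(25):
            a = rng.normal(50, 12, size=rng.integers(5, 60))
            b = rng.normal(55, 9, size=rng.integers(5, 60))
            raw = t_test_from_raw(a, b, variant=variant)
            summ = t_test_from_summary(
                SummaryStats.from_values(a), SummaryStats.from_values(b), variant=variant
            )
            assert raw.statistic == pytest.approx(summ.statistic, rel=1e-10)
            assert raw.p_value == pytest.approx(summ.p_value, rel=1e-10)

    def test_welch_differs_from_student_under_variance_imbalance(self):
        a = SummaryStats(10, 0.0, 1.0)
        b = SummaryStats(50, 1.0, 10.0)
        assert (
            t_test_from_summary(a, b, "welch").p_value
            != t_test_from_summary(a, b, "student").p_value
        )

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            t_test_from_raw([1.0], [1, 2, 3])


class TestPearson:
    def test_perfect_positive_line(self):
        x = np.arange(10.0)
        r = pearson_correlation(x, 2 * x + 1)
        assert r.estimate == pytest.approx(1.0)

    def test_perfect_negative_line(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x).estimate == pytest.approx(-1.0)

    def test_matches_from_definition_formula(self):
        """Seeded sample against a covariance/SD computation from scratch."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200)
        r = pearson_correlation(x, y)
        r_direct = float(
            np.sum((x - x.mean()) * (y - y.mean()))
            / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        )
        assert r.estimate == pytest.approx(r_direct, rel=1e-12)
        t = r_direct * math.sqrt(198 / (1 - r_direct**2))
        assert r.p_value == pytest.approx(2 * sps.t.sf(abs(t), 198), rel=1e-9)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        base = pearson_correlation(x, y).estimate
        assert pearson_correlation(3.2 * x + 7, y).estimate == pytest.approx(base)
        assert pearson_correlation(x, 0.1 * y - 4).estimate == pytest.approx(base)
        assert pearson_correlation(-x, y).estimate == pytest.approx(-base)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestAnovaLsd:
    def test_overall_f_matches_scipy_on_raw_groups(self):
        rng = np.random.default_rng(31)
        groups = {f"g{i}": rng.normal(i, 1.0, size=30) for i in range(3)}
        ours = anova_lsd({k: SummaryStats.from_values(v) for k, v in groups.items()})
        ref = sps.f_oneway(*groups.values())
        assert ours["overall"].statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert ours["overall"].p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_printed_age_anova(self):
        groups = {
            "RFH": SummaryStats(54, 55.92, 12.85),
            "ALH": SummaryStats(28, 60.44, 12.99),
            "MALToma": SummaryStats(43, 64.95, 12.16),
        }
        res = anova_lsd(groups)
        assert res["overall"].p_value < 0.05
        assert ("RFH", "MALToma") in res["pairwise"]
        assert res["pairwise"][("RFH", "MALToma")].p_value < 0.001


class TestPairwiseCorrection:
    @pytest.mark.parametrize(
        "n_groups, n_pairs, alpha_eff",
        [(2, 1, 0.05), (3, 3, 0.05 / 3), (4, 6, 0.05 / 6)],
    )
    def test_alpha_effective(self, n_groups, n_pairs, alpha_eff):
        rng = np.random.default_rng(1)
        groups = {f"g{i}": rng.normal(size=10) for i in range(n_groups)}
        res = pairwise_with_correction(
            groups, lambda a, b: t_test_from_raw(a, b), alpha=0.05
        )
        assert len(res) == n_pairs
        for r in res.values():
            assert r.alpha_effective == pytest.approx(alpha_eff)

    def test_significance_uses_effective_alpha(self):
        rng = np.random.default_rng(2)
        groups = {
            "a": rng.normal(0, 1, 40),
            "b": rng.normal(0, 1, 40),
            "c": rng.normal(3, 1, 40),
        }
        res = pairwise_with_correction(groups, lambda a, b: t_test_from_raw(a, b))
        for (g1, g2), r in res.items():
            assert r.significant == (r.p_value < 0.05 / 3)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_with_correction({"only": [1, 2]}, lambda a, b: None)


class TestSummarizeFixture:
    def test_printed_percentages(self, fx):
        s = summarize_cohort(fx)
        assert round(s.percent("RFH", "sex", "female"), 2) == 51.85
        assert round(s.percent("MALToma", "sex", "female"), 2) == 20.93
        assert round(s.percent("RFH", "laterality", "bilateral"), 1) == 40.7
        assert round(s.overall_percent("orbital_soft_tissue_any"), 1) == 78.4
        assert round(s.overall_percent("multi_compartment"), 1) == 47.2

    def test_key_p_values_match_printed(self, fx):
        s = summarize_cohort(fx)
        assert round(s.p_value("sex", "RFH&MALToma"), 3) == 0.002
        assert round(s.p_value("laterality", "overall"), 3) == 0.001
        for pair in ("RFH&ALH", "RFH&MALToma", "ALH&MALToma"):
            assert s.p_value("pain", pair) == pytest.approx(1.0)
        assert s.p_value("age", "RFH&MALToma") < 0.001

    def test_verified_rows_are_not_flagged(self, fx):
        s = summarize_cohort(fx)
        flagged = "\n".join(s.flags)
        assert "sex " not in flagged
        assert "laterality" not in flagged
        for line in s.flags:
            assert not line.startswith("pain RFH")

    def test_known_mismatches_are_flagged_not_forced(self, fx):
        """Rows whose printed p no method reproduces are reported as flags."""
        s = summarize_cohort(fx)
        assert any(f.startswith("age RFH&ALH") for f in s.flags)
        assert any(f.startswith("age ALH&MALToma") for f in s.flags)

    def test_p_formatting(self):
        assert format_p(0.0004) == "< 0.001"
        assert format_p(0.0016) == "0.002"
        assert format_p(1.0) == "1.000"

    def test_report_renders(self, fx):
        text = summarize_cohort(fx).to_text()
        assert "RFH (n=54)" in text
        assert "Overall multi_compartment: 59/125" in text


class TestSummarizeCohort:
    def test_counts_match_naive_record_tally(self, cohort125):
        s = summarize_cohort(cohort125)
        records = cohort125.records
        from lpdscore.cohort import Diagnosis, Sex, Site

        for g in Diagnosis:
            expected_f = sum(
                1 for r in records if r.diagnosis is g and r.sex is Sex.FEMALE
            )
            assert s.count(g, "sex", "female") == expected_f
            expected_orb = sum(
                1
                for r in records
                if r.diagnosis is g and Site.ORBITAL_SOFT_TISSUE in r.sites
            )
            assert s.count(g, "orbital_soft_tissue", "present") == expected_orb
        multi = sum(1 for r in records if len(r.sites) >= 2)
        assert s.overall_counts["multi_compartment"] == multi

    def test_single_group_cohort_skips_tests(self):
        from lpdscore import GeneratorConfig, generate
        from lpdscore.cohort import Diagnosis

        table = generate(
            GeneratorConfig(n_per_group={Diagnosis.RFH: 20, Diagnosis.ALH: 0,
                                         Diagnosis.MALTOMA: 0}),
            seed=4,
        )
        s = summarize_cohort(table)
        assert s.groups == (Diagnosis.RFH,)
        assert not s.tests
        assert any("single-group" in f for f in s.flags)

    def test_contingency_table_validation(self):
        with pytest.raises(ValueError):
            ContingencyTable([[1, 2]])
        with pytest.raises(ValueError):
            ContingencyTable([[1, -2], [3, 4]])
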