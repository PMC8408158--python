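"""One-tailed Wilcoxon rank-sum screen and BH FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pblgenomics.association import (
    Comparison,
    bh_fdr,
    default_comparisons,
    run_subcohort_screen,
    wilcoxon_rank_sum_one_tailed,
)


class TestExactRankSum:
    def test_two_vs_two_binary(self):
        # only 1 of C(4,2)=6 assignments puts both positives in group A
        p = wilcoxon_rank_sum_one_tailed([1, 1], [0, 0], "greater")
        assert p == pytest.approx(1 / 6)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum_one_tailed([1, 1, 0], [1, 1, 0]) <= 1.0
        assert wilcoxon_rank_sum_one_tailed([0, 0], [0, 0]) == 1.0

    def test_direction_reversal(self):
        p_g = wilcoxon_rank_sum_one_tailed([1, 1, 1], [0, 0, 0], "greater")
        p_l = wilcoxon_rank_sum_one_tailed([0, 0, 0], [1, 1, 1], "less")
        assert p_g == pytest.approx(p_l)

    def test_hiv_stat3_comparison(self):
        """7/15 positives vs 3/31 (the published STAT3-by-HIV table).

        The exact permutation tail equals the hypergeometric tail, 0.0079;
        the published p of 0.003 corresponds to the tie-corrected normal
        approximation of the rank-sum, reproduced by the asymptotic path.
        """
        a = [1] * 7 + [0] * 8
        b = [1] * 3 + [0] * 28
        p_exact = wilcoxon_rank_sum_one_tailed(a, b, "greater", method="exact")
        assert p_exact == pytest.approx(stats.hypergeom.sf(6, 46, 10, 15), rel=1e-9)
        p_asym = wilcoxon_rank_sum_one_tailed(a, b, "greater", method="asymptotic")
        assert p_asym == pytest.approx(0.003, abs=0.002)

    def test_matches_hypergeometric_tail_for_binary_data(self):
        """For 0/1 indicators the exact one-tailed rank-sum p equals the
        hypergeometric tail P(X >= count_A); brute force over all tables
        with N <= 12 (the full N <= 20 sweep runs in the acceptance suite)."""
        for n_total in range(2, 13):
            for n_a in range(1, n_total):
                n_b = n_total - n_a
                for ones_a in range(n_a + 1):
                    for ones_b in range(n_b + 1):
                        if ones_a + ones_b in (0, n_total):
                            continue  # constant data -> p = 1 by convention
                        a = [1] * ones_a + [0] * (n_a - ones_a)
                        b = [1] * ones_b + [0] * (n_b - ones_b)
                        p = wilcoxon_rank_sum_one_tailed(a, b, "greater")
                        expected = stats.hypergeom.sf(
                            ones_a - 1, n_total, ones_a + ones_b, n_a
                        )
                        assert p == pytest.approx(expected, rel=1e-9), (
                            n_a, n_b, ones_a, ones_b,
                        )

    def test_continuous_data_against_scipy_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            p = wilcoxon_rank_sum_one_tailed(a, b, "greater")
            expected = stats.mannwhitneyu(a, b, alternative="greater", method="exact")
            assert p == pytest.approx(expected.pvalue, rel=1e-9)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        a = (rng.random(60) < 0.5).astype(float)
        b = (rng.random(60) < 0.2).astype(float)
        p = wilcoxon_rank_sum_one_tailed(a, b, "greater")
        ref = stats.mannwhitneyu(a, b, alternative="greater", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_one_tailed([], [1.0])


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_step_up_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_max_q_equals_max_p(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1, size=25)
        assert bh_fdr(p).max() == pytest.approx(p.max())

    def test_invariant_under_input_permutation(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.0001, 1, size=30)
        perm = rng.permutation(30)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_rejects_zero_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])


class TestScreen:
    def test_all_zero_lesion_p_one(self):
        lesions = pd.DataFrame({"L": [0.0] * 10}, index=[f"s{i}" for i in range(10)])
        clinical = pd.DataFrame({"flag": [1.0] * 5 + [0.0] * 5}, index=lesions.index)
        res = run_subcohort_screen(
            lesions, clinical, [Comparison("c", "flag", 1, 0)]
        )
        assert res.iloc[0]["p_one_tailed"] == 1.0
        assert res.iloc[0]["q_bh"] == 1.0

    def test_missing_covariate_excluded_pairwise(self):
        lesions = pd.DataFrame({"L": [1.0, 1.0, 0.0, 0.0]}, index=list("abcd"))
        clinical = pd.DataFrame(
            {"flag": [1.0, np.nan, 0.0, 0.0]}, index=list("abcd")
        )
        res = run_subcohort_screen(lesions, clinical, [Comparison("c", "flag", 1, 0)])
        assert res.iloc[0]["n_a"] == 1 and res.iloc[0]["n_b"] == 2

    def test_empty_subgroup_skipped_with_warning(self):
        lesions = pd.DataFrame({"L": [1.0, 0.0]}, index=["a", "b"])
        clinical = pd.DataFrame({"flag": [1.0, 1.0]}, index=["a", "b"])
        with pytest.warns(UserWarning, match="skipped"):
            res = run_subcohort_screen(
                lesions, clinical, [Comparison("c", "flag", 1, 0)]
            )
        assert res.empty

    def test_planted_effect_detected(self):
        """A 40% vs 5% prevalence difference at n=30/arm is found at
        q < 0.1 (full 200-replicate power curve in the acceptance suite)."""
        rng = np.random.default_rng(7)
        n = 30
        group = np.repeat([1.0, 0.0], n)
        lesions = pd.DataFrame(
            {
                "planted": np.concatenate(
                    [(rng.random(n) < 0.4), (rng.random(n) < 0.05)]
                ).astype(float),
                **{
                    f"null{j}": (rng.random(2 * n) < 0.2).astype(float)
                    for j in range(5)
                },
            },
            index=[f"s{i}" for i in range(2 * n)],
        )
        clinical = pd.DataFrame({"flag": group}, index=lesions.index)
        res = run_subcohort_screen(lesions, clinical, [Comparison("c", "flag", 1, 0)])
        planted = res[res["lesion"] == "planted"].iloc[0]
        assert planted["significant"]

    def test_both_directions_produce_separate_rows(self):
        lesions = pd.DataFrame(
            {"L": [1.0, 1.0, 0.0, 0.0]}, index=list("abcd")
        )
        clinical = pd.DataFrame({"flag": [1.0, 1.0, 0.0, 0.0]}, index=list("abcd"))
        res = run_subcohort_screen(
            lesions, clinical, [Comparison("c", "flag", 1, 0)], both_directions=True
        )
        assert set(res["direction"]) == {"greater", "less"}

    def test_default_comparisons_run_on_synthetic_cohort(self, cohort):
        clin = cohort.clinical.set_index("sample_id").copy()
        lss_class = pd.Series(np.nan, index=clin.index, dtype=object)
        lss_class[(clin["lss_event"] == 1) & (clin["lss_months"] < 12)] = "short"
        lss_class[clin["lss_months"] > 24] = "long"
        clin["lss_class"] = lss_class
        gene_calls = cohort.tumor_calls[cohort.tumor_calls["gene"] != ""]
        lesions = (
            gene_calls.assign(x=1.0)
            .pivot_table(index="sample_id", columns="gene", values="x", fill_value=0.0)
            .reindex(clin.index, fill_value=0.0)
        )
        res = run_subcohort_screen(lesions, clin)
        assert len(res) > 0
        # q-values are BH-consistent within each comparison family
        for _, grp in res.groupby(["comparison", "direction"]):
            assert (grp["q_bh"] >= grp["p_one_tailed"] / len(grp) - 1e-12).all()
            assert grp["q_bh"].max() <= 1.0
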