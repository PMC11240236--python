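"""Filtering rules, Fisher exact vs enumeration, linkage screen, PCA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import fisher_two_sided
from conftest import make_site, sexlinked_site, small_config
from sexscan.seqio import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Cohort,
    Sample,
    Sex,
)
from sexscan.sexassoc import (
    FilterConfig,
    Pattern,
    bonferroni_threshold,
    filter_sites,
    genotype_pca,
    perfect_linkage_scan,
    sex_association_test,
)
from sexscan.simcohort import make_cohort, simulate_genotypes, simulate_haplotypes


class TestFilterSites:
    NO_DP = FilterConfig(min_dp=0, min_mean_dp=0)

    def test_low_call_rate_dropped(self, tiny_cohort):
        # 4/6 called = 0.67 < 0.8
        site = make_site([HET, HET, MISSING, MISSING, HOM_REF, HOM_REF])
        assert filter_sites([site], tiny_cohort, self.NO_DP) == []

    @pytest.mark.parametrize(
        "n_alt, kept", [(2, False), (3, True)]
    )  # 2/60 = 0.033 < 0.05 <= 3/60, boundary inclusive
    def test_maf_boundary_inclusive(self, n_alt, kept):
        cohort = Cohort(
            [Sample(f"M{i}", Sex.MALE) for i in range(15)]
            + [Sample(f"F{i}", Sex.FEMALE) for i in range(15)]
        )
        geno = [HET] * n_alt + [HOM_REF] * (30 - n_alt)
        out = filter_sites([make_site(geno)], cohort, self.NO_DP)
        assert bool(out) is kept

    def test_low_dp_call_set_missing_then_site_retained(self):
        # one call below min_dp becomes missing; 90/91 >= 0.8 keeps the site
        cohort = Cohort(
            [Sample(f"M{i}", Sex.MALE) for i in range(31)]
            + [Sample(f"F{i}", Sex.FEMALE) for i in range(60)]
        )
        geno = [HET] * 31 + [HOM_REF] * 40 + [HOM_ALT] * 20
        dp = np.full(91, 30, dtype=np.int32)
        dp[0] = 3
        (out,) = filter_sites([make_site(geno, dp=dp)], cohort)
        assert out.genotypes[0] == MISSING
        assert (out.genotypes[1:31] == HET).all()

    def test_low_mean_dp_dropped(self, tiny_cohort):
        geno = [HET, HOM_REF, HOM_ALT, HET, HOM_REF, HOM_ALT]
        dp = np.full(6, 5, dtype=np.int32)
        kept = filter_sites([make_site(geno, dp=dp)], tiny_cohort,
                            FilterConfig(min_dp=0, min_mean_dp=6))
        assert kept == []

    def test_missing_dp_skips_depth_filters_with_warning(self, tiny_cohort):
        site = make_site([HET, HOM_REF, HOM_ALT, HET, HOM_REF, HOM_ALT])
        with pytest.warns(UserWarning, match="DP"):
            assert len(filter_sites([site], tiny_cohort)) == 1


class TestFisher:
    def test_balanced_table_p_one(self):
        cohort = Cohort(
            [Sample(f"M{i}", Sex.MALE) for i in range(10)]
            + [Sample(f"F{i}", Sex.FEMALE) for i in range(10)]
        )
        site = make_site([HET] * 20)  # identical counts in both groups
        res = sex_association_test(site, cohort)
        assert res.p_value == pytest.approx(1.0)
        assert (res.table == [[10, 10], [10, 10]]).all()

    def test_two_by_two_enumeration_example(self):
        # table [[2,0],[0,2]]: 3 tables with these margins, probs 1/6, 4/6, 1/6
        cohort = Cohort([Sample("m", Sex.MALE), Sample("f", Sex.FEMALE)])
        site = make_site([HOM_REF, HOM_ALT])
        res = sex_association_test(site, cohort)
        assert res.p_value == pytest.approx(1 / 3)

    def test_fully_sexlinked_site_beats_genomewide_threshold(self):
        cohort = Cohort(
            [Sample(f"M{i}", Sex.MALE) for i in range(31)]
            + [Sample(f"F{i}", Sex.FEMALE) for i in range(60)]
        )
        res = sex_association_test(sexlinked_site(31, 60), cohort)
        assert (res.table == [[31, 31], [120, 0]]).all()
        assert res.neg_log10_p > 7.7

    def test_all_missing_group_is_untestable(self, tiny_cohort):
        site = make_site([MISSING] * 3 + [HOM_REF] * 3)
        res = sex_association_test(site, tiny_cohort)
        assert not res.testable

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        a=st.integers(0, 10),
        b=st.integers(0, 10),
        c=st.integers(0, 10),
        d=st.integers(0, 10),
    )
    def test_matches_exhaustive_enumeration(self, a, b, c, d):
        if a + c == 0 or b + d == 0 or a + b == 0 or c + d == 0:
            return
        from scipy.stats import fisher_exact

        p_impl = fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue
        p_oracle = fisher_two_sided([[a, b], [c, d]])
        assert p_impl == pytest.approx(p_oracle, rel=1e-8)


class TestBonferroni:
    def test_published_snp_count_gives_printed_threshold(self):
        assert round(bonferroni_threshold(0.01, 551_838), 1) == 7.7

    @pytest.mark.parametrize(
        "alpha, n, expected", [(0.05, 1, 1.301), (0.01, 100, 4.0)]
    )
    def test_closed_form_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected, abs=5e-4)

    def test_monotonicity(self):
        assert bonferroni_threshold(0.01, 1000) > bonferroni_threshold(0.01, 100)
        assert bonferroni_threshold(0.001, 100) > bonferroni_threshold(0.01, 100)

    @pytest.mark.parametrize("alpha, n", [(0.0, 10), (1.0, 10), (0.05, 0)])
    def test_invalid_inputs_rejected(self, alpha, n):
        with pytest.raises(ValueError):
            bonferroni_threshold(alpha, n)


class TestPerfectLinkage:
    @pytest.fixture
    def cohort91(self):
        return Cohort(
            [Sample(f"M{i}", Sex.MALE) for i in range(31)]
            + [Sample(f"F{i}", Sex.FEMALE) for i in range(60)]
        )

    def test_xy_pattern(self, cohort91):
        (pat,) = perfect_linkage_scan([sexlinked_site(31, 60)], cohort91)
        assert pat is Pattern.XY

    def test_zw_pattern_is_mirror(self, cohort91):
        site = make_site([HOM_REF] * 31 + [HET] * 60)
        (pat,) = perfect_linkage_scan([site], cohort91)
        assert pat is Pattern.ZW

    def test_single_violation_breaks_pattern(self, cohort91):
        geno = [HET] * 30 + [HOM_REF] + [HOM_REF] * 60
        (pat,) = perfect_linkage_scan([make_site(geno)], cohort91)
        assert pat is Pattern.NONE

    def test_mixed_female_homozygotes_break_pattern(self, cohort91):
        geno = [HET] * 31 + [HOM_REF] * 30 + [HOM_ALT] * 30
        (pat,) = perfect_linkage_scan([make_site(geno)], cohort91)
        assert pat is Pattern.NONE

    def test_missing_budget(self, cohort91):
        geno = [HET] * 30 + [MISSING] + [HOM_REF] * 60
        assert perfect_linkage_scan([make_site(geno)], cohort91) == [Pattern.NONE]
        assert perfect_linkage_scan(
            [make_site(geno)], cohort91, max_missing_calls=1
        ) == [Pattern.XY]

    def test_no_false_negatives_and_flagged_subset_under_error(self):
        cfg = small_config(genotype_error_rate=0.005, autosomal_snp_density=0.02)
        _, _, truth = simulate_haplotypes(cfg)
        cohort = make_cohort(cfg)
        sites = simulate_genotypes(truth, cohort, cfg)
        patterns = perfect_linkage_scan(sites, cohort)
        flagged = {s.pos for s, p in zip(sites, patterns) if p is Pattern.XY}
        assert flagged <= set(truth.sexlinked_snp_positions)

    def test_every_xy_site_is_genomewide_significant(self, cohort91, clean_sim):
        cfg, truth, cohort, sites = clean_sim
        patterns = perfect_linkage_scan(sites, cohort)
        threshold = bonferroni_threshold(0.01, len(sites))
        for s, p in zip(sites, patterns):
            if p is Pattern.XY:
                res = sex_association_test(s, cohort)
                assert res.neg_log10_p >= threshold


class TestPca:
    def test_identical_samples_score_zero(self, tiny_cohort):
        sites = [make_site([HET] * 6, pos=p) for p in (1, 2, 3)]
        with pytest.warns(UserWarning, match="rank"):
            scores, _ = genotype_pca(sites, tiny_cohort, k=2)
        assert np.allclose(scores, 0.0)

    def test_pc1_separates_sexes_on_sexlinked_chromosome(self, clean_sim):
        from sklearn.metrics import silhouette_score

        cfg, truth, cohort, sites = clean_sim
        scores, _ = genotype_pca(sites, cohort, k=2)
        labels = [s.sex.value for s in cohort.samples]
        assert silhouette_score(scores[:, :1], labels) > 0.8

    def test_score_vectors_orthogonal(self, clean_sim):
        _, _, cohort, sites = clean_sim
        scores, _ = genotype_pca(sites, cohort, k=4)
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(gram)).max()

    def test_sign_convention_deterministic(self, clean_sim):
        _, _, cohort, sites = clean_sim
        s1, _ = genotype_pca(sites, cohort, k=3)
        s2, _ = genotype_pca(sites, cohort, k=3)
        assert np.array_equal(s1, s2)
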