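"""Normalization, binning, region calling and gene classification."""

import numpy as np
import pandas as pd
import pytest

from sexscan.seqio import Cohort, GeneFeature, GenomicRegion, Sample, Sex
from sexscan.depthscan import (
    BinProfile,
    CallConfig,
    bin_profile,
    call_sex_specific_regions,
    continuous_span,
    intersect_genes,
    normalize_depth,
    normalize_matrix,
)


@pytest.fixture
def cohort4():
    return Cohort(
        [
            Sample("m1", Sex.MALE, 50.0),
            Sample("m2", Sex.MALE, 40.0),
            Sample("f1", Sex.FEMALE, 50.0),
            Sample("f2", Sex.FEMALE, 60.0),
        ]
    )


def profile_from_arrays(starts, male, female, bin_bp=50, chrom="chr18"):
    starts = np.asarray(starts)
    return BinProfile(
        chrom, bin_bp, starts, np.asarray(male, float), np.asarray(female, float),
        np.full(len(starts), bin_bp),
    )


class TestNormalize:
    def test_half_mean_gives_half(self, cohort4):
        df = pd.DataFrame(
            {"chrom": ["c"], "pos": [1], "m1": [25], "m2": [40], "f1": [0], "f2": [60]}
        )
        norm = normalize_depth(df, cohort4)
        assert norm.loc[0, "m1"] == pytest.approx(0.5)
        assert norm.loc[0, "m2"] == pytest.approx(1.0)
        assert norm.loc[0, "f1"] == 0.0

    def test_scale_invariance(self, cohort4):
        rng = np.random.default_rng(5)
        depth = rng.poisson(40, size=(200, 4)).astype(float)
        means = np.array([50.0, 40.0, 50.0, 60.0])
        base = normalize_matrix(depth, means)
        c = 3.7
        scaled = depth.copy()
        scaled[:, 1] *= c
        rescaled = normalize_matrix(scaled, means * [1, c, 1, 1])
        assert np.allclose(base, rescaled)

    def test_zero_mean_sample_excluded_with_warning(self):
        cohort = Cohort(
            [Sample("m1", Sex.MALE, 0.0), Sample("f1", Sex.FEMALE, 10.0)]
        )
        df = pd.DataFrame({"chrom": ["c"], "pos": [1], "m1": [5], "f1": [5]})
        with pytest.warns(UserWarning, match="m1"):
            norm = normalize_depth(df, cohort)
        assert "m1" not in norm.columns

    def test_mean_from_table_when_manifest_lacks_it(self):
        cohort = Cohort([Sample("m1", Sex.MALE), Sample("f1", Sex.FEMALE)])
        df = pd.DataFrame(
            {"chrom": "c", "pos": [1, 2], "m1": [10, 30], "f1": [20, 20]}
        )
        norm = normalize_depth(df, cohort)
        assert norm["m1"].tolist() == [0.5, 1.5]


class TestBinProfile:
    def test_uniform_depth_gives_unit_bins(self, cohort4):
        pos = np.arange(1, 101)
        df = pd.DataFrame({"chrom": "c", "pos": pos})
        for sid in cohort4.ids:
            df[sid] = 1.0
        prof = bin_profile(df, cohort4, bin_bp=50)
        assert list(prof.starts) == [0, 50]
        assert np.allclose(prof.mean_norm_depth_male, 1.0)
        assert np.allclose(prof.mean_norm_depth_female, 1.0)

    def test_hemizygous_bin_pattern(self, cohort4):
        pos = np.arange(1, 51)
        df = pd.DataFrame({"chrom": "c", "pos": pos})
        df["m1"] = 0.5
        df["m2"] = 0.5
        df["f1"] = 0.0
        df["f2"] = 0.0
        prof = bin_profile(df, cohort4, bin_bp=50)
        assert prof.mean_norm_depth_male[0] == pytest.approx(0.5)
        assert prof.mean_norm_depth_female[0] == 0.0

    def test_empty_table_gives_zero_bins(self, cohort4):
        df = pd.DataFrame({"chrom": pd.Series(dtype=str), "pos": pd.Series(dtype=int)})
        for sid in cohort4.ids:
            df[sid] = pd.Series(dtype=float)
        prof = bin_profile(df, cohort4)
        assert len(prof.starts) == 0

    def test_invalid_bin_width_rejected(self, cohort4):
        df = pd.DataFrame({"chrom": ["c"], "pos": [1]})
        for sid in cohort4.ids:
            df[sid] = 1.0
        with pytest.raises(ValueError):
            bin_profile(df, cohort4, bin_bp=0)


class TestCallRegions:
    def test_exact_bins_give_printed_y1(self):
        starts = np.arange(3_187_350, 3_187_750, 50)
        prof = profile_from_arrays(starts, [0.5] * 8, [0.0] * 8)
        (region,) = call_sex_specific_regions(prof)
        assert (region.start, region.end, region.label) == (
            3_187_350,
            3_187_750,
            "Y1",
        )
        assert region.length == 400

    def test_800bp_gap_not_merged(self):
        # Y2/Y3 geometry: two runs separated by 800 bp of diploid bins
        starts = np.concatenate(
            [
                np.arange(3_195_150, 3_196_250, 50),
                np.arange(3_196_250, 3_197_050, 50),
                np.arange(3_197_050, 3_198_050, 50),
            ]
        )
        male = np.concatenate([np.full(22, 0.5), np.full(16, 1.0), np.full(20, 0.5)])
        female = np.concatenate([np.zeros(22), np.full(16, 1.0), np.zeros(20)])
        regions = call_sex_specific_regions(profile_from_arrays(starts, male, female))
        assert [(r.start, r.end) for r in regions] == [
            (3_195_150, 3_196_250),
            (3_197_050, 3_198_050),
        ]

    def test_short_gap_merged(self):
        starts = np.array([0, 50, 100, 250, 300])  # 100-bp hole at [150,250)
        prof = profile_from_arrays(starts, [0.5] * 5, [0.0] * 5)
        (region,) = call_sex_specific_regions(prof)
        assert (region.start, region.end) == (0, 350)

    def test_equal_depth_gives_no_regions(self):
        starts = np.arange(0, 1_000, 50)
        ones = np.ones(len(starts))
        assert call_sex_specific_regions(profile_from_arrays(starts, ones, ones)) == []

    def test_min_length_drops_single_bin(self):
        prof = profile_from_arrays([1_000], [0.5], [0.0])
        assert call_sex_specific_regions(prof) == []

    def test_monotone_in_female_max(self):
        starts = np.arange(0, 2_000, 50)
        rng = np.random.default_rng(9)
        male = np.full(len(starts), 0.5)
        female = rng.uniform(0, 0.1, size=len(starts))
        tight = call_sex_specific_regions(
            profile_from_arrays(starts, male, female), CallConfig(female_max=0.03)
        )
        loose = call_sex_specific_regions(
            profile_from_arrays(starts, male, female), CallConfig(female_max=0.08)
        )
        covered = lambda r, calls: any(
            c.start <= r.start and r.end <= c.end for c in calls
        )
        assert all(covered(r, loose) for r in tight)

    def test_mirrored_mode_calls_female_specific(self):
        starts = np.arange(0, 400, 50)
        prof = profile_from_arrays(starts, [0.0] * 8, [0.5] * 8)
        (region,) = call_sex_specific_regions(prof, mirrored=True)
        assert region.label == "W1"

    def test_labels_in_genomic_order(self):
        starts = np.concatenate([np.arange(0, 400, 50), np.arange(5_000, 5_400, 50)])
        prof = profile_from_arrays(starts, [0.5] * 16, [0.0] * 16)
        regions = call_sex_specific_regions(prof)
        assert [r.label for r in regions] == ["Y1", "Y2"]
        assert regions[0].start < regions[1].start


class TestSpanAndGenes:
    def test_printed_coordinates_span_10700(self):
        regions = [
            GenomicRegion("chr18", 3_187_350, 3_187_750, "Y1"),
            GenomicRegion("chr18", 3_195_150, 3_196_250, "Y2"),
            GenomicRegion("chr18", 3_197_050, 3_198_050, "Y3"),
        ]
        assert continuous_span(regions) == 10_700

    def test_single_region_span_is_own_length(self):
        assert continuous_span([GenomicRegion("c", 10, 60)]) == 50

    def test_touching_regions(self):
        assert continuous_span(
            [GenomicRegion("c", 0, 50), GenomicRegion("c", 50, 100)]
        ) == 100

    def test_mixed_chromosomes_rejected(self):
        with pytest.raises(ValueError):
            continuous_span([GenomicRegion("a", 0, 1), GenomicRegion("b", 0, 1)])

    def test_gene_classification_matches_published_layout(self):
        regions = [
            GenomicRegion("chr18", 3_187_350, 3_187_750, "Y1"),
            GenomicRegion("chr18", 3_195_150, 3_196_250, "Y2"),
            GenomicRegion("chr18", 3_197_050, 3_198_050, "Y3"),
        ]
        genes = [
            GeneFeature("ephx1", "+", GenomicRegion("chr18", 3_184_083, 3_188_235)),
            GeneFeature("tcf24", "+", GenomicRegion("chr18", 3_190_352, 3_193_193)),
            GeneFeature("far", "+", GenomicRegion("chr18", 9_000_000, 9_001_000)),
        ]
        by_id = {c.gene.id: c for c in intersect_genes(regions, genes)}
        assert by_id["ephx1"].status == "overlaps"
        assert by_id["ephx1"].regions == ("Y1",)
        assert by_id["tcf24"].status == "between"
        assert by_id["tcf24"].regions == ("Y1", "Y2")
        assert by_id["far"].status == "outside"

    def test_empty_gene_list(self):
        assert intersect_genes([GenomicRegion("c", 0, 10)], []) == []
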