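"""Stage 1: SNP filtering, sex association, perfect-linkage screen, PCA.

The association test is a two-sided Fisher exact test on the per-site
allele-count 2x2 table (rows male/female, columns REF/ALT allele).  At a
fully sex-linked SNP in a reasonably sized cohort any valid test
saturates; the decisive criterion for sex linkage is the genotype
*pattern* screen: every heterogametic-sex individual heterozygous and
every homogametic-sex individual homozygous for the same allele
(XY_pattern, or the sex-mirrored ZW_pattern).
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from sexscan.seqio import HET, HOM_ALT, HOM_REF, MISSING, Cohort, VariantSite


class Pattern(str, enum.Enum):
    NONE = "none"
    XY = "XY_pattern"
    ZW = "ZW_pattern"


@dataclass
class FilterConfig:
    """Site/genotype filters applied before any scan.

    Defaults match widely used vcftools-style hard filters:
    ``max_missing`` is the minimum *called* fraction per site (0.8 keeps
    sites called in >=80% of samples), ``maf_min`` the minimum minor
    allele frequency, ``min_dp`` a per-genotype depth floor (calls below
    it are set missing before the site-level filters), ``min_mean_dp``
    the per-site mean depth floor over called genotypes.  Thresholds are
    inclusive: values equal to the threshold are kept.
    """

    max_missing: float = 0.8
    maf_min: float = 0.05
    min_dp: int = 4
    min_mean_dp: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must lie in [0, 1]")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must lie in [0, 0.5]")
        if self.min_dp < 0 or self.min_mean_dp < 0:
            raise ValueError("depth floors must be >= 0")


@dataclass
class AssocResult:
    site: VariantSite
    #: rows male/female, columns REF/ALT allele counts over called genotypes
    table: np.ndarray
    p_value: float
    neg_log10_p: float
    perfect_linkage: Pattern = Pattern.NONE
    passes_genomewide: bool = False
    testable: bool = True


def filter_sites(
    sites: Sequence[VariantSite],
    cohort: Cohort,
    config: FilterConfig | None = None,
) -> list[VariantSite]:
    """Apply genotype-level then site-level hard filters, preserving order.

    Genotype calls with DP < ``min_dp`` are set missing first; a site is
    then kept iff called fraction >= ``max_missing``, MAF >= ``maf_min``
    and mean DP over called genotypes >= ``min_mean_dp``.  If sites lack
    DP the depth criteria are skipped with a warning.
    """
    if config is None:
        config = FilterConfig()
    warned = False
    kept: list[VariantSite] = []
    n = len(cohort)
    for site in sites:
        geno = site.genotypes
        dp = site.dp
        if dp is None and (config.min_dp > 0 or config.min_mean_dp > 0):
            if not warned:
                warnings.warn(
                    "sites lack DP; per-genotype and mean-depth filters skipped",
                    stacklevel=2,
                )
                warned = True
        if dp is not None and config.min_dp > 0:
            low = (dp >= 0) & (dp < config.min_dp) & (geno != MISSING)
            if low.any():
                geno = geno.copy()
                geno[low] = MISSING
                site = VariantSite(
                    site.chrom, site.pos, site.ref, site.alt, geno, dp
                )
        called = geno != MISSING
        n_called = int(called.sum())
        if n_called / n < config.max_missing:
            continue
        if n_called == 0:
            continue
        alt_count = int(geno[called].sum())  # codes 0/1/2 are ALT dosages
        af = alt_count / (2 * n_called)
        if min(af, 1 - af) < config.maf_min:
            continue
        if dp is not None and config.min_mean_dp > 0:
            usable = called & (dp >= 0)
            if usable.any() and dp[usable].mean() < config.min_mean_dp:
                continue
        kept.append(site)
    return kept


def allele_count_table(site: VariantSite, cohort: Cohort) -> np.ndarray:
    """2x2 allele counts: rows male/female, columns REF/ALT."""
    table = np.zeros((2, 2), dtype=np.int64)
    for row, idx in enumerate((cohort.male_idx, cohort.female_idx)):
        geno = site.genotypes[idx]
        called = geno != MISSING
        alt = int(geno[called].sum())
        total = 2 * int(called.sum())
        table[row] = (total - alt, alt)
    return table


def sex_association_test(site: VariantSite, cohort: Cohort) -> AssocResult:
    """Two-sided Fisher exact test on the allele-count table."""
    table = allele_count_table(site, cohort)
    if table[0].sum() == 0 or table[1].sum() == 0:
        return AssocResult(
            site, table, p_value=float("nan"), neg_log10_p=float("nan"),
            testable=False,
        )
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    p = min(max(p, 5e-324), 1.0)
    return AssocResult(site, table, p_value=p, neg_log10_p=-math.log10(p))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Genome-wide -log10(p) threshold, -log10(alpha / n_tests)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return -math.log10(alpha / n_tests)


def _genotype_matrix(sites: Sequence[VariantSite]) -> np.ndarray:
    return np.stack([s.genotypes for s in sites]) if sites else np.empty((0, 0), np.int8)


def perfect_linkage_scan(
    sites: Sequence[VariantSite],
    cohort: Cohort,
    max_missing_calls: int = 0,
) -> list[Pattern]:
    """Flag each site's sex-linkage genotype pattern.

    XY_pattern: every non-missing male call het AND every non-missing
    female call the *same* homozygote, with at most ``max_missing_calls``
    missing calls per sex group.  ZW_pattern is the sex mirror.
    """
    cohort.require_both_sexes()
    if not sites:
        return []
    geno = _genotype_matrix(sites)
    male = geno[:, cohort.male_idx]
    female = geno[:, cohort.female_idx]

    def group_pattern(het_grp: np.ndarray, hom_grp: np.ndarray) -> np.ndarray:
        het_missing = (het_grp == MISSING).sum(axis=1)
        hom_missing = (hom_grp == MISSING).sum(axis=1)
        het_called = het_grp.shape[1] - het_missing
        hom_called = hom_grp.shape[1] - hom_missing
        all_het = ((het_grp == HET) | (het_grp == MISSING)).all(axis=1)
        hom_ref_ok = ((hom_grp == HOM_REF) | (hom_grp == MISSING)).all(axis=1)
        hom_alt_ok = ((hom_grp == HOM_ALT) | (hom_grp == MISSING)).all(axis=1)
        return (
            all_het
            & (hom_ref_ok | hom_alt_ok)
            & (het_missing <= max_missing_calls)
            & (hom_missing <= max_missing_calls)
            & (het_called > 0)
            & (hom_called > 0)
        )

    xy = group_pattern(male, female)
    zw = group_pattern(female, male)
    out = []
    for i in range(len(sites)):
        if xy[i]:
            out.append(Pattern.XY)
        elif zw[i]:
            out.append(Pattern.ZW)
        else:
            out.append(Pattern.NONE)
    return out


def genotype_pca(
    sites: Sequence[VariantSite], cohort: Cohort, k: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Sample scores for the top-k principal components of genotype dosage.

    Dosages (0/1/2, missing imputed to the site mean) are column-centered
    and decomposed by SVD; scores are ordered by decreasing eigenvalue
    with a deterministic sign convention (the largest-magnitude loading
    of each component is positive).  Returns ``(scores, eigenvalues)``
    with scores of shape (n_samples, k_effective).
    """
    if len(cohort) < 2:
        raise ValueError("PCA needs >= 2 samples")
    if not sites:
        raise ValueError("PCA needs >= 1 site")
    geno = _genotype_matrix(sites).astype(float).T  # samples x sites
    geno[geno == MISSING] = np.nan
    col_mean = np.nanmean(geno, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    idx = np.where(np.isnan(geno))
    geno[idx] = col_mean[idx[1]]
    centered = geno - geno.mean(axis=0)

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if k > rank:
        warnings.warn(
            f"requested {k} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        k = rank
    scores = u[:, :k] * s[:k]
    eigenvalues = (s[:k] ** 2) / (centered.shape[0] - 1)
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    return scores, eigenvalues
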