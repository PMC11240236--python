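"""Stage 2: windowed Fst between sex groups and within-group diversity.

Two Fst estimators are provided.  ``wright`` is the textbook
(H_T - H_S)/H_T with H_T = 2*pbar*(1-pbar) at the count-weighted mean
frequency and H_S the count-weighted mean of the subpopulation
heterozygosities; it is bounded in [0, 1] and convenient for closed-form
checks.  ``wc84`` is the Weir & Cockerham variance-components estimator
(theta) computed from genotype data including observed heterozygosity;
per-site components (a, b, c) are kept so windows combine as the
ratio of sums  sum(a) / sum(a + b + c), which is how vcftools reports
windowed weighted Fst.  Small negative wc84 values are expected noise.

Nucleotide diversity theta-pi uses the unbiased per-site estimator
2p(1-p) * 2n/(2n-1) (equal to the mean number of pairwise differences
among the 2n called alleles) summed over SNPs and divided by the window
width in bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from sexscan.seqio import HET, MISSING, Cohort, Sex, VariantSite


@dataclass
class FstComponents:
    """Per-site Fst building blocks.

    For ``wc84``: Weir & Cockerham a (among-population), b (among
    individuals within populations) and c (within individuals); the
    single-site estimate is a / (a + b + c).  For ``wright`` the
    components are (H_T - H_S, H_S, 0) so the same ratio applies.
    """

    a: float
    b: float
    c: float

    @property
    def fst(self) -> float:
        denom = self.a + self.b + self.c
        return float("nan") if denom == 0 else self.a / denom


@dataclass
class WindowStat:
    chrom: str
    start: int
    end: int
    n_sites: int
    fst: float | None
    pi_male: float | None = None
    pi_female: float | None = None


@dataclass
class GroupSiteStats:
    """Per-group summary of one site: alt frequency, diploid count, het freq."""

    p: float
    n: int
    het: float


def group_site_stats(site: VariantSite, idx: np.ndarray) -> GroupSiteStats | None:
    geno = site.genotypes[idx]
    called = geno != MISSING
    n = int(called.sum())
    if n == 0:
        return None
    alt = int(geno[called].sum())
    het = float((geno[called] == HET).mean())
    return GroupSiteStats(p=alt / (2 * n), n=n, het=het)


def site_fst(
    male: GroupSiteStats,
    female: GroupSiteStats,
    estimator: str = "wc84",
) -> FstComponents | None:
    """Fst components for one site; None when monomorphic overall."""
    if male.n < 1 or female.n < 1:
        raise ValueError("each group needs >= 1 diploid individual")
    n_m, n_f = male.n, female.n
    p_m, p_f = male.p, female.p
    pbar = (2 * n_m * p_m + 2 * n_f * p_f) / (2 * n_m + 2 * n_f)
    if pbar in (0.0, 1.0):
        return None
    if estimator == "wright":
        h_t = 2 * pbar * (1 - pbar)
        h_s = (
            2 * n_m * 2 * p_m * (1 - p_m) + 2 * n_f * 2 * p_f * (1 - p_f)
        ) / (2 * n_m + 2 * n_f)
        return FstComponents(a=h_t - h_s, b=h_s, c=0.0)
    if estimator == "wc84":
        r = 2
        nbar = (n_m + n_f) / r
        nc = (r * nbar - (n_m**2 + n_f**2) / (r * nbar)) / (r - 1)
        s2 = (n_m * (p_m - pbar) ** 2 + n_f * (p_f - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n_m * male.het + n_f * female.het) / (r * nbar)
        if nbar <= 1 or nc == 0:
            return None
        a = (nbar / nc) * (
            s2
            - (1 / (nbar - 1))
            * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - ((r - 1) / r) * s2
            - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        return FstComponents(a=a, b=b, c=c)
    raise ValueError(f"unknown estimator {estimator!r}")


def site_fst_from_genotypes(
    site: VariantSite, cohort: Cohort, estimator: str = "wc84"
) -> FstComponents | None:
    """Convenience wrapper computing group stats then components."""
    m = group_site_stats(site, cohort.male_idx)
    f = group_site_stats(site, cohort.female_idx)
    if m is None or f is None:
        return None  # a group entirely missing: skip the site
    return site_fst(m, f, estimator)


def _windows(start: int, stop: int, window_bp: int, step_bp: int):
    w_start = (start // step_bp) * step_bp
    while w_start < stop:
        yield w_start, w_start + window_bp
        w_start += step_bp


def windowed_scan(
    sites: Sequence[VariantSite],
    cohort: Cohort,
    window_bp: int = 10_000,
    step_bp: int | None = None,
    estimator: str = "wc84",
    chrom_length: int | None = None,
) -> list[WindowStat]:
    """Windowed Fst over sorted sites of one chromosome.

    Sliding windows of ``window_bp`` advanced by ``step_bp`` (tiling when
    equal; default step = window/2).  wc84 combines per-site components
    as a ratio of sums; wright combines as the mean of per-site values.
    Windows with no usable (polymorphic, both-groups-called) sites carry
    ``fst=None``.
    """
    cohort.require_both_sexes()
    if step_bp is None:
        step_bp = window_bp // 2
    if step_bp > window_bp:
        raise ValueError("step_bp must not exceed window_bp")
    if not sites:
        return []
    chroms = {s.chrom for s in sites}
    if len(chroms) > 1:
        raise ValueError(f"windowed_scan expects one chromosome, got {sorted(chroms)}")
    chrom = sites[0].chrom
    pos0 = np.array([s.pos - 1 for s in sites])
    comps = [site_fst_from_genotypes(s, cohort, estimator) for s in sites]
    stop = chrom_length if chrom_length is not None else int(pos0.max()) + 1

    out: list[WindowStat] = []
    for w_start, w_end in _windows(0, stop, window_bp, step_bp):
        mask = (pos0 >= w_start) & (pos0 < w_end)
        idx = np.flatnonzero(mask)
        usable = [comps[i] for i in idx if comps[i] is not None]
        if not usable:
            out.append(WindowStat(chrom, w_start, w_end, 0, None))
            continue
        if estimator == "wc84":
            a = sum(c.a for c in usable)
            abc = sum(c.a + c.b + c.c for c in usable)
            fst = a / abc if abc != 0 else None
        else:
            fst = float(np.mean([c.fst for c in usable]))
        out.append(WindowStat(chrom, w_start, w_end, len(usable), fst))
    return out


def site_pi(p: float, n_alleles: int) -> float:
    """Unbiased per-site diversity 2p(1-p) * n/(n-1) over n called alleles."""
    if n_alleles < 2:
        raise ValueError("need >= 2 called alleles")
    return 2 * p * (1 - p) * n_alleles / (n_alleles - 1)


def windowed_pi(
    sites: Sequence[VariantSite],
    cohort: Cohort,
    sex: Sex,
    window_bp: int = 10_000,
    chrom_length: int | None = None,
) -> list[WindowStat]:
    """Per-bp nucleotide diversity of one sex group in tiling windows.

    Window theta-pi = (sum of per-SNP unbiased heterozygosities) /
    window_bp; invariant sites contribute zero, so dividing by the window
    width (not the SNP count) gives a per-bp quantity.
    """
    idx = cohort.indices_of(sex)
    if len(idx) < 2:
        raise ValueError(f"group {sex.value} needs >= 2 diploid samples")
    if not sites:
        return []
    chrom = sites[0].chrom
    pos0 = np.array([s.pos - 1 for s in sites])
    vals = np.zeros(len(sites))
    for i, s in enumerate(sites):
        g = group_site_stats(s, idx)
        if g is None or g.n < 2:
            continue
        vals[i] = site_pi(g.p, 2 * g.n)
    stop = chrom_length if chrom_length is not None else int(pos0.max()) + 1
    out = []
    for w_start, w_end in _windows(0, stop, window_bp, window_bp):
        mask = (pos0 >= w_start) & (pos0 < w_end)
        pi = float(vals[mask].sum()) / window_bp
        field = "pi_male" if sex is Sex.MALE else "pi_female"
        ws = WindowStat(chrom, w_start, w_end, int(mask.sum()), None)
        setattr(ws, field, pi)
        out.append(ws)
    return out
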