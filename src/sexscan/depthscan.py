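"""Stage 3: depth normalization, 50-bp binning, hemizygous-region calling.

The ploidy signal: dividing each sample's per-site depth by its
genome-wide mean depth puts diploid-shared sequence at ~1.0 regardless
of how deeply the sample was sequenced.  A segment carried only on the
Y haplotype then sits at ~0.5 in XY males (one copy instead of two) and
at ~0 in XX females (no copy at all).  Group means over 50-bp bins are
contrasted against a female ceiling and a male hemizygous band, and
qualifying bins are merged into candidate regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from sexscan.seqio import Cohort, GeneFeature, GenomicRegion


@dataclass
class CallConfig:
    """Thresholds turning a binned depth contrast into called regions.

    ``female_max`` is the normalized-depth ceiling for the absent group
    (0.05 tolerates sporadic mismapped reads), the male hemizygous band
    [``male_low``, ``male_high``] brackets the expected 0.5,
    ``max_merge_gap_bp`` bridges short runs of non-qualifying bins (150
    bp = 3 bins absorbs boundary dilution and Poisson dips without
    bridging genuinely separate regions), and ``min_region_bp`` drops
    single-bin noise calls.
    """

    female_max: float = 0.05
    male_low: float = 0.3
    male_high: float = 0.7
    min_region_bp: int = 200
    max_merge_gap_bp: int = 150

    def __post_init__(self) -> None:
        if not 0 <= self.female_max < self.male_low < self.male_high:
            raise ValueError(
                "need 0 <= female_max < male_low < male_high"
            )
        if self.min_region_bp < 1 or self.max_merge_gap_bp < 0:
            raise ValueError("invalid region length / merge gap")


def normalize_depth(depth_df: pd.DataFrame, cohort: Cohort) -> pd.DataFrame:
    """Divide each sample's depths by its genome-wide mean depth.

    Mean depths come from the cohort manifest; for samples without one,
    the column mean of the table is used.  Samples whose mean depth is 0
    are excluded with a warning.
    """
    import warnings

    out = depth_df[["chrom", "pos"]].copy()
    means = cohort.mean_depths
    for j, sid in enumerate(cohort.ids):
        mean = means[j]
        if np.isnan(mean):
            mean = float(depth_df[sid].mean())
        if mean <= 0:
            warnings.warn(f"sample {sid} has zero mean depth; excluded", stacklevel=2)
            continue
        out[sid] = depth_df[sid].to_numpy(dtype=np.float64) / mean
    return out


def normalize_matrix(depth: np.ndarray, mean_depths: np.ndarray) -> np.ndarray:
    """Array-level normalization: depth[:, j] / mean_depths[j]."""
    mean_depths = np.asarray(mean_depths, dtype=np.float64)
    if np.any(mean_depths <= 0):
        raise ValueError("mean depths must be > 0")
    return depth / mean_depths[None, :]


@dataclass
class BinProfile:
    """Group-mean normalized depth in fixed-width bins tiling a chromosome."""

    chrom: str
    bin_bp: int
    #: bin start coordinates (0-based, multiples of bin_bp)
    starts: np.ndarray
    mean_norm_depth_male: np.ndarray
    mean_norm_depth_female: np.ndarray
    n_sites: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.starts + self.bin_bp,
                "n_sites": self.n_sites,
                "male_mean": self.mean_norm_depth_male,
                "female_mean": self.mean_norm_depth_female,
            }
        )


def bin_profile(
    norm_df: pd.DataFrame, cohort: Cohort, bin_bp: int = 50
) -> BinProfile:
    """Average normalized depth over samples x sites per 50-bp bin.

    Bins are indexed by ``(pos - 1) // bin_bp`` so they tile the
    chromosome without overlap; bins containing no sites are omitted
    (equivalently: undefined).
    """
    if bin_bp <= 0:
        raise ValueError("bin_bp must be > 0")
    chroms = norm_df["chrom"].unique()
    if len(chroms) > 1:
        raise ValueError(f"bin_profile expects one chromosome, got {list(chroms)}")
    male_ids = [cohort.ids[i] for i in cohort.male_idx if cohort.ids[i] in norm_df]
    female_ids = [cohort.ids[i] for i in cohort.female_idx if cohort.ids[i] in norm_df]
    if not male_ids or not female_ids:
        raise ValueError("need normalized depths for >= 1 sample of each sex")
    if len(norm_df) == 0:
        return BinProfile(
            str(chroms[0]) if len(chroms) else "",
            bin_bp,
            np.empty(0, int),
            np.empty(0),
            np.empty(0),
            np.empty(0, int),
        )
    bin_idx = (norm_df["pos"].to_numpy() - 1) // bin_bp
    grouped = norm_df.assign(_bin=bin_idx).groupby("_bin", sort=True)
    male_mean = grouped[male_ids].mean().mean(axis=1)
    female_mean = grouped[female_ids].mean().mean(axis=1)
    n_sites = grouped.size()
    starts = (male_mean.index.to_numpy() * bin_bp).astype(int)
    return BinProfile(
        chrom=str(chroms[0]),
        bin_bp=bin_bp,
        starts=starts,
        mean_norm_depth_male=male_mean.to_numpy(),
        mean_norm_depth_female=female_mean.to_numpy(),
        n_sites=n_sites.to_numpy(),
    )


def call_sex_specific_regions(
    profile: BinProfile,
    config: CallConfig | None = None,
    mirrored: bool = False,
    label_prefix: str | None = None,
) -> list[GenomicRegion]:
    """Call hemizygous/absent regions from the binned group contrast.

    A bin qualifies iff the absent-group mean is <= ``female_max`` and
    the hemizygous-group mean lies within [``male_low``, ``male_high``]
    (by default females absent / males hemizygous; ``mirrored=True``
    swaps the roles to call W/X-specific regions).  Maximal runs of
    qualifying bins are merged across gaps <= ``max_merge_gap_bp``;
    regions shorter than ``min_region_bp`` are dropped.  Labels are
    assigned in genomic order (Y1, Y2, ... or W1, W2, ...).
    """
    if config is None:
        config = CallConfig()
    if config.min_region_bp < profile.bin_bp:
        raise ValueError("min_region_bp must be >= bin width")
    hemi = profile.mean_norm_depth_male
    absent = profile.mean_norm_depth_female
    if mirrored:
        hemi, absent = absent, hemi
    if label_prefix is None:
        label_prefix = "W" if mirrored else "Y"
    qualifies = (
        (absent <= config.female_max)
        & (hemi >= config.male_low)
        & (hemi <= config.male_high)
    )
    starts = profile.starts[qualifies]
    if starts.size == 0:
        return []
    # merge qualifying bins whose gap (in bp between bin intervals) <= max gap
    intervals: list[list[int]] = [[int(starts[0]), int(starts[0]) + profile.bin_bp]]
    for s in starts[1:]:
        s = int(s)
        if s - intervals[-1][1] <= config.max_merge_gap_bp:
            intervals[-1][1] = s + profile.bin_bp
        else:
            intervals.append([s, s + profile.bin_bp])
    regions = [
        GenomicRegion(profile.chrom, s, e)
        for s, e in intervals
        if e - s >= config.min_region_bp
    ]
    return [
        GenomicRegion(r.chrom, r.start, r.end, f"{label_prefix}{i + 1}")
        for i, r in enumerate(regions)
    ]


def continuous_span(regions: Sequence[GenomicRegion]) -> int:
    """bp from the first region's start to the last region's end."""
    if not regions:
        raise ValueError("need >= 1 region")
    chroms = {r.chrom for r in regions}
    if len(chroms) > 1:
        raise ValueError(f"regions span multiple chromosomes: {sorted(chroms)}")
    return max(r.end for r in regions) - min(r.start for r in regions)


@dataclass
class GeneClassification:
    gene: GeneFeature
    #: "overlaps", "between", or "outside"
    status: str
    #: labels of the overlapped region(s), or the flanking pair for "between"
    regions: tuple[str, ...]


def intersect_genes(
    regions: Sequence[GenomicRegion], genes: Sequence[GeneFeature]
) -> list[GeneClassification]:
    """Classify each gene against the called regions.

    A gene *overlaps* a region when the half-open intersection is
    nonempty; it is *between* two consecutive regions when it has no
    overlap but lies entirely inside the gap separating them; otherwise
    it is *outside*.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    out: list[GeneClassification] = []
    for gene in genes:
        hits = tuple(r.label for r in ordered if r.overlaps(gene.interval))
        if hits:
            out.append(GeneClassification(gene, "overlaps", hits))
            continue
        between: tuple[str, ...] = ()
        for left, right in zip(ordered, ordered[1:]):
            if (
                left.chrom == right.chrom == gene.interval.chrom
                and left.end <= gene.interval.start
                and gene.interval.end <= right.start
            ):
                between = (left.label, right.label)
                break
        out.append(
            GeneClassification(gene, "between" if between else "outside", between)
        )
    return out
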