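"""Synthetic XY cohort generator with a machine-readable truth set.

The generator emulates a whole-genome resequencing experiment on a
diploid cohort of XY males and XX females mapped against the male
reference, at the level where the pipeline's signals live:

* a reference-frame chromosome carrying *male-specific* (Y-only)
  segments — hemizygous in males (copy number 1), absent in females
  (copy number 0) — and fully sex-linked SNPs at which every error-free
  male is heterozygous and every female homozygous for the X allele;
* autosomal-style background SNPs in Hardy–Weinberg proportions at a
  per-site sampled allele frequency;
* per-site sequencing depth drawn Poisson(copy_number * lambda * s_i)
  with a lognormal per-sample coverage factor s_i;
* independent per-call genotype error (symmetric state flip) and
  missingness.

No reads and no aligner: the observable the downstream depth scan uses
is the per-site depth table, so depth is simulated directly.  All draws
are derived from ``SimConfig.seed`` via fixed-purpose child seeds, so a
given config reproduces byte-identical outputs regardless of call order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from sexscan.seqio import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    Cohort,
    GenomicRegion,
    Sample,
    Sex,
    VariantSite,
    write_depth_table,
    write_fasta,
    write_sex_manifest,
    write_vcf,
)

#: the three-segment architecture reported for the male-specific region
#: (400 / 1,100 / 1,000 bp with an 800-bp gap between the last two)
DEFAULT_MALE_SEGMENTS = (
    (3_187_350, 3_187_750),
    (3_195_150, 3_196_250),
    (3_197_050, 3_198_050),
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# fixed child-seed tags so each stage has its own independent stream
_SEED_COHORT = 1
_SEED_HAPLO = 2
_SEED_GENO = 3
_SEED_DEPTH = 4


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults reproduce the reference study's conditions: 31 XY males and
    60 XX females, the printed Y1/Y2/Y3 segment coordinates on a 3.3-Mb
    chromosome, 232 fully sex-linked SNPs, background SNP density
    matching ~551,838 SNPs over a ~586.5-Mb genome, and 20x per-copy
    coverage (≈40x diploid) with mild per-sample coverage variation.
    """

    chrom_length: int = 3_300_000
    chrom_name: str = "chr18"
    n_males: int = 31
    n_females: int = 60
    #: reads per site per haploid copy (lambda)
    per_copy_coverage: float = 20.0
    #: sd of the lognormal per-sample coverage factor (mean 1)
    sample_coverage_factor_sd: float = 0.1
    male_specific_segments: tuple[tuple[int, int], ...] = DEFAULT_MALE_SEGMENTS
    x_specific_segments: tuple[tuple[int, int], ...] = ()
    n_sexlinked_snps: int = 232
    #: per-bp rate of background (autosomal-style) SNPs
    autosomal_snp_density: float = 0.00094
    genotype_missing_rate: float = 0.02
    genotype_error_rate: float = 0.005
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise SimConfigError("seed is mandatory")
        if self.per_copy_coverage < 0:
            raise SimConfigError("per_copy_coverage must be >= 0")
        for rate in (
            self.genotype_missing_rate,
            self.genotype_error_rate,
        ):
            if not 0.0 <= rate <= 1.0:
                raise SimConfigError("rates must lie in [0, 1]")
        if self.autosomal_snp_density < 0:
            raise SimConfigError("autosomal_snp_density must be >= 0")
        self.male_specific_segments = tuple(
            tuple(seg) for seg in self.male_specific_segments
        )
        self.x_specific_segments = tuple(
            tuple(seg) for seg in self.x_specific_segments
        )
        _check_segments(self.male_specific_segments, self.chrom_length)
        _check_segments(self.x_specific_segments, self.chrom_length)

    def rng(self, tag: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), tag])


def _check_segments(segments, chrom_length: int) -> None:
    prev_end = -1
    for start, end in sorted(segments):
        if not (0 <= start < end <= chrom_length):
            raise SimConfigError(
                f"segment [{start},{end}) outside [0,{chrom_length})"
            )
        if start < prev_end:
            raise SimConfigError("segments must be mutually disjoint")
        prev_end = end


@dataclass
class TruthSet:
    """Ground truth for one simulated cohort."""

    #: 1-based positions of fully sex-linked SNPs (reference frame)
    sexlinked_snp_positions: list[int]
    #: X (ref) and Y (alt) alleles per sex-linked position
    sexlinked_alleles: dict[int, tuple[str, str]]
    male_specific_regions: list[GenomicRegion]
    #: per-sample id -> (sex, coverage factor)
    samples: dict[str, tuple[str, float]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "sexlinked_snp_positions": list(map(int, self.sexlinked_snp_positions)),
            "sexlinked_alleles": {
                str(p): list(a) for p, a in self.sexlinked_alleles.items()
            },
            "male_specific_regions": [
                {"chrom": r.chrom, "start": r.start, "end": r.end, "label": r.label}
                for r in self.male_specific_regions
            ],
            "samples": {k: [v[0], v[1]] for k, v in self.samples.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        raw = json.loads(Path(path).read_text())
        return cls(
            sexlinked_snp_positions=list(map(int, raw["sexlinked_snp_positions"])),
            sexlinked_alleles={
                int(p): (a[0], a[1]) for p, a in raw["sexlinked_alleles"].items()
            },
            male_specific_regions=[
                GenomicRegion(r["chrom"], r["start"], r["end"], r["label"])
                for r in raw["male_specific_regions"]
            ],
            samples={k: (v[0], float(v[1])) for k, v in raw["samples"].items()},
        )


def make_cohort(config: SimConfig) -> Cohort:
    """Sampled cohort with lognormal coverage factors baked into mean depth.

    The manifest mean depth is the sample's expected genome-wide depth,
    2 * lambda * s_i (the genome is overwhelmingly diploid-shared).
    """
    rng = config.rng(_SEED_COHORT)
    n = config.n_males + config.n_females
    sd = config.sample_coverage_factor_sd
    if sd > 0:
        # lognormal with mean exactly 1
        factors = rng.lognormal(mean=-0.5 * np.log(1 + sd**2), sigma=np.sqrt(np.log(1 + sd**2)), size=n)
    else:
        factors = np.ones(n)
    samples = []
    for i in range(config.n_males):
        samples.append(
            Sample(f"M{i + 1:03d}", Sex.MALE, 2 * config.per_copy_coverage * factors[i])
        )
    for j in range(config.n_females):
        samples.append(
            Sample(
                f"F{j + 1:03d}",
                Sex.FEMALE,
                2 * config.per_copy_coverage * factors[config.n_males + j],
            )
        )
    return Cohort(samples)


def coverage_factors(cohort: Cohort, config: SimConfig) -> np.ndarray:
    """Per-sample coverage factors s_i implied by the manifest depths."""
    return cohort.mean_depths / (2 * config.per_copy_coverage)


def simulate_haplotypes(config: SimConfig) -> tuple[str, str, TruthSet]:
    """Simulate the X and Y chromosome sequences and the truth set.

    The reference coordinate frame is the Y (male) chromosome of length
    ``chrom_length``.  Male-specific segments are Y-only: the X sequence
    is the reference with those intervals deleted (and any configured
    X-specific insertions added).  Sex-linked SNPs are X/Y fixed
    differences outside the segments; the X base is the REF allele, so
    the emitted reference-frame sequence (Y) carries the ALT base there.
    """
    rng = config.rng(_SEED_HAPLO)
    y = rng.choice(_BASES, size=config.chrom_length)

    in_segment = np.zeros(config.chrom_length, dtype=bool)
    for start, end in config.male_specific_segments:
        in_segment[start:end] = True

    eligible = np.flatnonzero(~in_segment)
    if config.n_sexlinked_snps > len(eligible):
        raise SimConfigError("more sex-linked SNPs requested than eligible sites")
    snp_pos0 = np.sort(
        rng.choice(eligible, size=config.n_sexlinked_snps, replace=False)
    )

    alleles: dict[int, tuple[str, str]] = {}
    x_frame = y.copy()
    for p0 in snp_pos0:
        y_base = y[p0].decode()
        x_base = rng.choice([b for b in "ACGT" if b != y_base])
        x_frame[p0] = x_base.encode()
        alleles[int(p0) + 1] = (str(x_base), y_base)

    # X chromosome: reference frame minus Y-only segments, plus X-only inserts
    keep = ~in_segment
    x_parts = x_frame[keep]
    x_seq = x_parts.tobytes().decode()
    for start, end in sorted(config.x_specific_segments, reverse=True):
        length = end - start
        insert = rng.choice(_BASES, size=length).tobytes().decode()
        pos = min(start, len(x_seq))
        x_seq = x_seq[:pos] + insert + x_seq[pos:]

    regions = [
        GenomicRegion(config.chrom_name, start, end, f"Y{i + 1}")
        for i, (start, end) in enumerate(sorted(config.male_specific_segments))
    ]
    cohort = make_cohort(config)
    factors = coverage_factors(cohort, config)
    truth = TruthSet(
        sexlinked_snp_positions=[int(p) + 1 for p in snp_pos0],
        sexlinked_alleles=alleles,
        male_specific_regions=regions,
        samples={
            s.id: (s.sex.value, float(f)) for s, f in zip(cohort.samples, factors)
        },
    )
    return x_seq, y.tobytes().decode(), truth


def simulate_genotypes(
    truth: TruthSet, cohort: Cohort, config: SimConfig
) -> list[VariantSite]:
    """Simulate per-site genotype calls (sex-linked + background SNPs).

    Error-free calls are het in every male and hom_ref in every female at
    sex-linked sites; background sites draw from Hardy–Weinberg at a
    uniform(0.05, 0.95) allele frequency.  Genotype error (symmetric flip
    to one of the two other states) and missingness are applied
    independently per call.
    """
    rng = config.rng(_SEED_GENO)
    n = len(cohort)
    male = np.zeros(n, dtype=bool)
    male[cohort.male_idx] = True

    in_segment = np.zeros(config.chrom_length, dtype=bool)
    for start, end in config.male_specific_segments:
        in_segment[start:end] = True
    taken = np.zeros(config.chrom_length, dtype=bool)
    sl_pos0 = np.array(truth.sexlinked_snp_positions, dtype=int) - 1
    taken[sl_pos0] = True

    n_auto = rng.poisson(config.autosomal_snp_density * config.chrom_length)
    eligible = np.flatnonzero(~in_segment & ~taken)
    n_auto = min(n_auto, len(eligible))
    auto_pos0 = np.sort(rng.choice(eligible, size=n_auto, replace=False))

    positions = np.concatenate([sl_pos0, auto_pos0])
    is_sexlinked = np.concatenate(
        [np.ones(len(sl_pos0), bool), np.zeros(n_auto, bool)]
    )
    order = np.argsort(positions, kind="stable")
    positions, is_sexlinked = positions[order], is_sexlinked[order]
    n_sites = len(positions)

    geno = np.empty((n_sites, n), dtype=np.int8)
    # sex-linked pattern
    geno[is_sexlinked] = np.where(male, HET, HOM_REF)[None, :]
    # background HWE draws
    n_bg = int((~is_sexlinked).sum())
    freqs = rng.uniform(0.05, 0.95, size=n_bg)
    geno[~is_sexlinked] = rng.binomial(2, freqs[:, None], size=(n_bg, n)).astype(
        np.int8
    )

    # symmetric state-flip errors, then missingness
    if config.genotype_error_rate > 0:
        err = rng.random((n_sites, n)) < config.genotype_error_rate
        shift = rng.integers(1, 3, size=(n_sites, n), dtype=np.int8)
        geno = np.where(err, (geno + shift) % 3, geno).astype(np.int8)
    if config.genotype_missing_rate > 0:
        miss = rng.random((n_sites, n)) < config.genotype_missing_rate
        geno[miss] = MISSING

    lam = cohort.mean_depths  # expected diploid depth per sample
    dp = rng.poisson(np.broadcast_to(lam, (n_sites, n))).astype(np.int32)

    ref_alt = _site_alleles(positions, is_sexlinked, truth, config)
    sites = [
        VariantSite(
            config.chrom_name,
            int(p) + 1,
            ra[0],
            ra[1],
            geno[i],
            dp[i],
        )
        for i, (p, ra) in enumerate(zip(positions, ref_alt))
    ]
    return sites


def _site_alleles(positions, is_sexlinked, truth, config):
    rng = config.rng(_SEED_GENO + 100)
    out = []
    for p, sl in zip(positions, is_sexlinked):
        if sl:
            out.append(truth.sexlinked_alleles[int(p) + 1])
        else:
            ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
            out.append((str(ref), str(alt)))
    return out


def copy_number(
    truth: TruthSet, sex: Sex, start: int, end: int
) -> np.ndarray:
    """Reference-frame copy number over [start, end) for one sex."""
    cn = np.full(end - start, 2, dtype=np.int8)
    for region in truth.male_specific_regions:
        lo, hi = max(region.start, start), min(region.end, end)
        if lo < hi:
            cn[lo - start : hi - start] = 1 if sex is Sex.MALE else 0
    return cn


def simulate_depth(
    truth: TruthSet,
    cohort: Cohort,
    config: SimConfig,
    start: int = 0,
    end: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-site depths over reference frame [start, end).

    Returns ``(positions, depth)`` with 1-based positions and an
    ``(n_sites, n_samples)`` int32 matrix: depth ~ Poisson(cn * lambda *
    s_i) with cn = 2 on shared sequence and 1 (males) / 0 (females)
    inside male-specific segments.
    """
    if end is None:
        end = config.chrom_length
    if not (0 <= start < end <= config.chrom_length):
        raise SimConfigError(f"depth interval [{start},{end}) out of bounds")
    rng = config.rng(_SEED_DEPTH)
    n_sites = end - start
    positions = np.arange(start + 1, end + 1)
    if config.per_copy_coverage == 0:
        return positions, np.zeros((n_sites, len(cohort)), dtype=np.int32)
    factors = coverage_factors(cohort, config)
    depth = np.empty((n_sites, len(cohort)), dtype=np.int32)
    for j, sample in enumerate(cohort.samples):
        cn = copy_number(truth, sample.sex, start, end)
        lam = config.per_copy_coverage * factors[j]
        depth[:, j] = rng.poisson(cn.astype(np.float64) * lam)
    return positions, depth


def depth_frame(
    positions: np.ndarray, depth: np.ndarray, cohort: Cohort, chrom: str
) -> pd.DataFrame:
    """Assemble a depth matrix into the samtools-depth-style DataFrame."""
    df = pd.DataFrame({"chrom": chrom, "pos": positions})
    for j, sid in enumerate(cohort.ids):
        df[sid] = depth[:, j]
    return df


def write_simulation(
    config: SimConfig,
    outdir: str | Path,
    depth_start: int = 0,
    depth_end: int | None = None,
) -> dict[str, Path]:
    """Run the full generator and write all artefacts to ``outdir``.

    Emits ``genome.fa`` (X and Y records), ``cohort.tsv``, ``truth.json``,
    ``sim.vcf`` and ``sim.depth.tsv``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x_seq, y_seq, truth = simulate_haplotypes(config)
    cohort = make_cohort(config)
    sites = simulate_genotypes(truth, cohort, config)
    positions, depth = simulate_depth(
        truth, cohort, config, depth_start, depth_end
    )
    paths = {
        "fasta": outdir / "genome.fa",
        "cohort": outdir / "cohort.tsv",
        "truth": outdir / "truth.json",
        "vcf": outdir / "sim.vcf",
        "depth": outdir / "sim.depth.tsv",
    }
    write_fasta(
        {f"{config.chrom_name}_Y": y_seq, f"{config.chrom_name}_X": x_seq},
        paths["fasta"],
    )
    write_sex_manifest(cohort, paths["cohort"])
    truth.to_json(paths["truth"])
    write_vcf(sites, cohort, paths["vcf"])
    write_depth_table(
        depth_frame(positions, depth, cohort, config.chrom_name), paths["depth"]
    )
    return paths
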