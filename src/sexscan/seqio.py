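"""Readers/writers for external formats and the shared domain types.

Coordinate conventions
----------------------
Internal intervals (:class:`GenomicRegion`, gene intervals, BED) are
0-based half-open, so ``length == end - start``.  VCF positions and the
depth-table positions stay 1-based as in their source formats; GFF3
1-based inclusive coordinates are converted to half-open on read.

Genotypes are encoded as small integers (:data:`HOM_REF`, :data:`HET`,
:data:`HOM_ALT`, :data:`MISSING`) in a per-site ``numpy`` vector ordered
like the cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING = -1

GT_NAMES = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class SeqIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class Sample:
    id: str
    sex: Sex
    #: genome-wide mean depth (reads per site); None when not yet known
    mean_depth: float | None = None


@dataclass
class Cohort:
    """Ordered collection of sexed samples.

    Sample order fixes the column order of genotype vectors and of the
    depth table; ids must be unique.
    """

    samples: list[Sample]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqIOError(f"duplicate sample ids: {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.samples]

    def indices_of(self, sex: Sex) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if s.sex is sex], dtype=int
        )

    @property
    def male_idx(self) -> np.ndarray:
        return self.indices_of(Sex.MALE)

    @property
    def female_idx(self) -> np.ndarray:
        return self.indices_of(Sex.FEMALE)

    @property
    def n_males(self) -> int:
        return len(self.male_idx)

    @property
    def n_females(self) -> int:
        return len(self.female_idx)

    def require_both_sexes(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise SeqIOError(
                f"group statistics need >=1 male and >=1 female; got "
                f"{self.n_males} males, {self.n_females} females"
            )

    @property
    def mean_depths(self) -> np.ndarray:
        """Per-sample mean depths; NaN where unknown."""
        return np.array(
            [np.nan if s.mean_depth is None else s.mean_depth for s in self.samples]
        )


@dataclass
class VariantSite:
    """One biallelic site with per-sample genotype calls.

    ``pos`` is 1-based (VCF convention); ``genotypes`` and ``dp`` are
    vectors in cohort order.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: np.ndarray
    dp: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise SeqIOError(f"pos must be >= 1, got {self.pos}")
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)


@dataclass(frozen=True)
class GenomicRegion:
    """Half-open interval [start, end) with an optional label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqIOError(
                f"invalid region {self.chrom}:[{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_pos(self, pos1: int) -> bool:
        """Whether a 1-based position falls inside the region."""
        return self.start <= pos1 - 1 < self.end


@dataclass
class GeneFeature:
    id: str
    strand: str
    interval: GenomicRegion


# ---------------------------------------------------------------------------
# sex manifest
# ---------------------------------------------------------------------------

def read_sex_manifest(path: str | Path) -> Cohort:
    """Read a TSV of ``sample_id  sex  [mean_depth]`` into a Cohort."""
    samples: list[Sample] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise SeqIOError(f"{path}:{lineno}: expected >=2 columns")
        sex_txt = fields[1].strip().lower()
        try:
            sex = Sex(sex_txt)
        except ValueError:
            # tolerate common single-letter encodings
            sex = {"m": Sex.MALE, "f": Sex.FEMALE}.get(sex_txt)
            if sex is None:
                raise SeqIOError(f"{path}:{lineno}: unknown sex {fields[1]!r}")
        depth = float(fields[2]) if len(fields) > 2 and fields[2] != "" else None
        if depth is not None and depth < 0:
            raise SeqIOError(f"{path}:{lineno}: negative mean depth")
        samples.append(Sample(fields[0], sex, depth))
    return Cohort(samples)


def write_sex_manifest(cohort: Cohort, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in cohort.samples:
            depth = "" if s.mean_depth is None else f"{s.mean_depth:.6g}"
            fh.write(f"{s.id}\t{s.sex.value}\t{depth}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(
    path: str | Path,
    cohort: Cohort,
    multiallelic: str = "drop",
) -> Iterator[VariantSite]:
    """Yield VariantSites from a VCF, reordered to cohort sample order.

    Genotype mapping: 0/0 -> hom_ref, 0/1 or 1/0 -> het, 1/1 -> hom_alt,
    ./. -> missing.  Multiallelic records are dropped by default or split
    into one biallelic site per alternate allele (``multiallelic="split"``,
    genotypes carrying another alternate set missing).
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise ValueError(f"multiallelic must be 'drop' or 'split', got {multiallelic!r}")

    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    missing_ids = [i for i in cohort.ids if i not in header_samples]
    if missing_ids:
        raise SeqIOError(f"samples absent from VCF header: {missing_ids}")
    order = np.array([header_samples.index(i) for i in cohort.ids])

    has_dp = "DP" in {line["ID"] for line in vcf.header_iter() if line["HeaderType"] == "FORMAT"}

    for recno, var in enumerate(vcf, start=1):
        alts = var.ALT
        if len(alts) == 0:
            continue
        gts = np.array([g[:2] for g in var.genotypes], dtype=int)[order]
        if np.any(gts > len(alts)):
            raise SeqIOError(
                f"{path}: record {recno} ({var.CHROM}:{var.POS}): "
                f"GT allele index out of range"
            )
        dp = None
        if has_dp:
            try:
                raw = var.format("DP")
            except KeyError:
                raw = None
            if raw is not None:
                dp = raw.astype(np.int32).reshape(-1)[order]
                dp = np.where(dp < 0, -1, dp)
        if len(alts) == 1:
            yield _site_from_alleles(var.CHROM, var.POS, var.REF, alts[0], gts, dp, 1)
        elif multiallelic == "split":
            for ai, alt in enumerate(alts, start=1):
                yield _site_from_alleles(var.CHROM, var.POS, var.REF, alt, gts, dp, ai)
        # else: drop


def _site_from_alleles(chrom, pos, ref, alt, gts, dp, alt_index) -> VariantSite:
    codes = np.full(len(gts), MISSING, dtype=np.int8)
    a, b = gts[:, 0], gts[:, 1]
    called = (a >= 0) & (b >= 0)
    # alleles other than ref / the chosen alt make the call missing
    usable = called & np.isin(a, (0, alt_index)) & np.isin(b, (0, alt_index))
    n_alt = (a == alt_index).astype(int) + (b == alt_index).astype(int)
    codes[usable] = np.select(
        [n_alt[usable] == 0, n_alt[usable] == 1], [HOM_REF, HET], HOM_ALT
    )
    return VariantSite(chrom, pos, ref, alt, codes, dp)


def write_vcf(
    sites: Iterable[VariantSite], cohort: Cohort, path: str | Path
) -> None:
    """Write biallelic sites as a minimal VCFv4.2 with GT (and DP if set)."""
    gt_txt = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    sites = list(sites)
    contigs = sorted({s.chrom for s in sites})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.ids)
            + "\n"
        )
        for s in sites:
            if s.dp is None:
                fmt = "GT"
                calls = [gt_txt[int(g)] for g in s.genotypes]
            else:
                fmt = "GT:DP"
                calls = [
                    f"{gt_txt[int(g)]}:{int(d) if d >= 0 else '.'}"
                    for g, d in zip(s.genotypes, s.dp)
                ]
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# depth table (samtools-depth style: chrom, pos, one column per sample)
# ---------------------------------------------------------------------------

def read_depth_table(path: str | Path, cohort: Cohort) -> pd.DataFrame:
    """Read a per-site depth TSV into a DataFrame.

    Columns: ``chrom``, ``pos`` (1-based) and one integer column per
    cohort sample, in cohort order.  A leading ``#``-prefixed header line
    is skipped.  Row order is preserved.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            dtype={0: str},
        )
    except pd.errors.ParserError as exc:
        raise SeqIOError(f"{path}: ragged depth table: {exc}") from exc
    if df.shape[1] != 2 + len(cohort):
        raise SeqIOError(
            f"{path}: expected {2 + len(cohort)} columns "
            f"(chrom, pos, {len(cohort)} samples), found {df.shape[1]}"
        )
    df.columns = ["chrom", "pos", *cohort.ids]
    for col in df.columns[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 1
            raise SeqIOError(f"{path}: non-numeric value in column {col!r}, data row {row}")
        if (vals % 1 != 0).any():
            row = int(np.flatnonzero((vals % 1 != 0).to_numpy())[0]) + 1
            raise SeqIOError(f"{path}: non-integer depth in column {col!r}, data row {row}")
        df[col] = vals.astype(np.int64)
    depths = df[cohort.ids].to_numpy()
    if (depths < 0).any():
        raise SeqIOError(f"{path}: negative depth values")
    if (df["pos"] < 1).any():
        raise SeqIOError(f"{path}: positions must be >= 1")
    return df


def write_depth_table(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(map(str, df.columns)) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------

def write_bed(regions: Sequence[GenomicRegion], path: str | Path) -> None:
    """Write regions as sorted 0-based half-open BED."""
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    with open(path, "w") as fh:
        for r in ordered:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.label}\n")


def read_bed(path: str | Path) -> list[GenomicRegion]:
    regions = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        if len(f) < 3:
            raise SeqIOError(f"{path}:{lineno}: expected >=3 BED columns")
        regions.append(
            GenomicRegion(f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "")
        )
    return regions


def read_gff3(path: str | Path, featuretype: str = "gene") -> list[GeneFeature]:
    """Read gene features from GFF3, converting to half-open intervals.

    Features with start > end are rejected with a warning rather than an
    error, since they occasionally appear in hand-edited annotations.
    """
    import warnings

    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneFeature] = []
    for feat in db.features_of_type(featuretype, order_by=("seqid", "start")):
        if feat.start > feat.end:
            warnings.warn(
                f"{path}: feature {feat.id} has start > end; skipped", stacklevel=2
            )
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneFeature(
                id=gene_id,
                strand=feat.strand,
                interval=GenomicRegion(feat.seqid, feat.start - 1, feat.end, gene_id),
            )
        )
    return genes


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
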