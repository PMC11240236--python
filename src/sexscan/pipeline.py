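"""Orchestration: run the full discovery chain and emit a report.

Glue only — every statistic lives in its stage module.  Stages: genotype
filtering, sex association + perfect-linkage screen, windowed Fst and
theta-pi, depth normalization/binning/region calling, gene intersection,
then a heterogamety verdict (XY / ZW / none) from the colocalization of
perfectly sex-linked SNPs with sex-specific depth regions.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from sexscan import depthscan, popgen, sexassoc, seqio
from sexscan.depthscan import CallConfig
from sexscan.seqio import Cohort, GenomicRegion, Sex, VariantSite
from sexscan.sexassoc import FilterConfig, Pattern

logger = logging.getLogger("sexscan")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    vcf: str
    depth: str
    sex_manifest: str
    outdir: str
    gff: str | None = None
    fasta: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    alpha: float = 0.01
    window_bp: int = 10_000
    step_bp: int = 5_000
    bin_bp: int = 50
    call: CallConfig = field(default_factory=CallConfig)
    min_sites: int = 5
    max_span_bp: int = 10_000_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        filt = FilterConfig(**raw.pop("filter", {}))
        call = CallConfig(**raw.pop("call", {}))
        return cls(filter=filt, call=call, **raw)

    def validate(self) -> None:
        for name in ("vcf", "depth", "sex_manifest"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        for name in ("gff", "fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")


def infer_system(
    patterns: Sequence[Pattern],
    sites: Sequence[VariantSite],
    male_specific: Sequence[GenomicRegion],
    female_specific: Sequence[GenomicRegion],
    min_sites: int = 5,
    max_span_bp: int = 10_000_000,
) -> str:
    """Heterogamety verdict from pattern sites and depth regions.

    ``XY`` iff at least ``min_sites`` XY-pattern SNPs colocalize (within
    ``max_span_bp`` on the same chromosome) with >= 1 male-specific
    depth region; ``ZW`` is the mirror with ZW-pattern SNPs and
    female-specific regions; else ``none``.
    """

    def colocalizes(pattern: Pattern, regions: Sequence[GenomicRegion]) -> bool:
        for region in regions:
            close = [
                s
                for s, p in zip(sites, patterns)
                if p is pattern
                and s.chrom == region.chrom
                and min(
                    abs(s.pos - 1 - region.start), abs(s.pos - 1 - region.end)
                )
                <= max_span_bp
            ]
            if len(close) >= min_sites:
                return True
        return False

    if colocalizes(Pattern.XY, male_specific):
        return "XY"
    if colocalizes(Pattern.ZW, female_specific):
        return "ZW"
    return "none"


def run_full_scan(config: RunConfig) -> dict:
    """Execute filter -> association -> Fst/pi -> depth scan -> genes.

    Writes assoc.tsv, fst.tsv, pi_male.tsv, pi_female.tsv, bins.tsv,
    regions.bed, genes_classified.tsv (when a GFF is given), report.json
    and a MANIFEST of completed stages.  Deterministic given identical
    inputs and config.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    manifest = outdir / "MANIFEST"

    def finish_stage(name: str, t0: float) -> None:
        completed.append(name)
        manifest.write_text("\n".join(completed) + "\n")
        logger.info("stage %s done in %.1fs", name, time.time() - t0)

    report: dict = {"system": "none"}
    try:
        stage = "load"
        t0 = time.time()
        cohort = seqio.read_sex_manifest(config.sex_manifest)
        cohort.require_both_sexes()
        sites = list(seqio.read_vcf(config.vcf, cohort))
        depth_df = seqio.read_depth_table(config.depth, cohort)
        finish_stage(stage, t0)

        stage = "filter"
        t0 = time.time()
        filtered = sexassoc.filter_sites(sites, cohort, config.filter)
        report["n_sites_input"] = len(sites)
        report["n_sites_filtered"] = len(filtered)
        finish_stage(stage, t0)

        stage = "assoc"
        t0 = time.time()
        patterns = sexassoc.perfect_linkage_scan(filtered, cohort)
        results = [sexassoc.sex_association_test(s, cohort) for s in filtered]
        threshold = sexassoc.bonferroni_threshold(
            config.alpha, max(len(filtered), 1)
        )
        for res, pat in zip(results, patterns):
            res.perfect_linkage = pat
            res.passes_genomewide = (
                res.testable and res.neg_log10_p >= threshold
            )
        _write_assoc(results, outdir / "assoc.tsv")
        report["neg_log10_threshold"] = round(threshold, 4)
        report["n_significant"] = sum(r.passes_genomewide for r in results)
        report["n_xy_pattern"] = sum(p is Pattern.XY for p in patterns)
        report["n_zw_pattern"] = sum(p is Pattern.ZW for p in patterns)
        finish_stage(stage, t0)

        stage = "popgen"
        t0 = time.time()
        by_chrom: dict[str, list[VariantSite]] = {}
        for s in filtered:
            by_chrom.setdefault(s.chrom, []).append(s)
        fst_rows, pi_m_rows, pi_f_rows = [], [], []
        for chrom, chrom_sites in sorted(by_chrom.items()):
            fst_rows += popgen.windowed_scan(
                chrom_sites, cohort, config.window_bp, config.step_bp
            )
            if cohort.n_males >= 2:
                pi_m_rows += popgen.windowed_pi(
                    chrom_sites, cohort, Sex.MALE, config.window_bp
                )
            if cohort.n_females >= 2:
                pi_f_rows += popgen.windowed_pi(
                    chrom_sites, cohort, Sex.FEMALE, config.window_bp
                )
        _write_windows(fst_rows, "fst", outdir / "fst.tsv")
        _write_windows(pi_m_rows, "pi_male", outdir / "pi_male.tsv")
        _write_windows(pi_f_rows, "pi_female", outdir / "pi_female.tsv")
        defined = [w for w in fst_rows if w.fst is not None]
        top = sorted(defined, key=lambda w: w.fst, reverse=True)[:5]
        report["top_fst_windows"] = [
            {"chrom": w.chrom, "start": w.start, "end": w.end, "fst": round(w.fst, 4)}
            for w in top
        ]
        finish_stage(stage, t0)

        stage = "depthscan"
        t0 = time.time()
        norm = depthscan.normalize_depth(depth_df, cohort)
        male_regions: list[GenomicRegion] = []
        female_regions: list[GenomicRegion] = []
        bin_frames = []
        for chrom, chrom_norm in norm.groupby("chrom", sort=True):
            profile = depthscan.bin_profile(chrom_norm, cohort, config.bin_bp)
            bin_frames.append(profile.to_frame())
            male_regions += depthscan.call_sex_specific_regions(
                profile, config.call
            )
            female_regions += depthscan.call_sex_specific_regions(
                profile, config.call, mirrored=True
            )
        pd.concat(bin_frames, ignore_index=True).to_csv(
            outdir / "bins.tsv", sep="\t", index=False
        )
        male_regions = _relabel(male_regions, "Y")
        female_regions = _relabel(female_regions, "W")
        seqio.write_bed(male_regions + female_regions, outdir / "regions.bed")
        report["male_specific_regions"] = [
            {"chrom": r.chrom, "start": r.start, "end": r.end, "label": r.label}
            for r in male_regions
        ]
        report["n_male_specific_regions"] = len(male_regions)
        report["n_female_specific_regions"] = len(female_regions)
        if male_regions and len({r.chrom for r in male_regions}) == 1:
            report["male_region_span_bp"] = depthscan.continuous_span(male_regions)
        finish_stage(stage, t0)

        stage = "genes"
        t0 = time.time()
        if config.gff is not None:
            genes = seqio.read_gff3(config.gff)
            classes = depthscan.intersect_genes(male_regions, genes)
            with open(outdir / "genes_classified.tsv", "w") as fh:
                fh.write("gene\tchrom\tstart\tend\tstatus\tregions\n")
                for c in classes:
                    iv = c.gene.interval
                    fh.write(
                        f"{c.gene.id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t"
                        f"{c.status}\t{','.join(c.regions)}\n"
                    )
            report["n_genes_classified"] = len(classes)
        finish_stage(stage, t0)

        stage = "verdict"
        t0 = time.time()
        report["system"] = infer_system(
            patterns,
            filtered,
            male_regions,
            female_regions,
            config.min_sites,
            config.max_span_bp,
        )
        finish_stage(stage, t0)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    return report


def _relabel(regions: list[GenomicRegion], prefix: str) -> list[GenomicRegion]:
    ordered = sorted(regions, key=lambda r: (r.chrom, r.start))
    return [
        GenomicRegion(r.chrom, r.start, r.end, f"{prefix}{i + 1}")
        for i, r in enumerate(ordered)
    ]


def _write_assoc(results, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tmale_ref\tmale_alt\tfemale_ref\tfemale_alt\t"
            "p\tneg_log10_p\tpattern\tsignificant\n"
        )
        for r in results:
            t = r.table
            fh.write(
                f"{r.site.chrom}\t{r.site.pos}\t{r.site.ref}\t{r.site.alt}\t"
                f"{t[0, 0]}\t{t[0, 1]}\t{t[1, 0]}\t{t[1, 1]}\t"
                f"{r.p_value:.6g}\t{r.neg_log10_p:.4f}\t"
                f"{r.perfect_linkage.value}\t{int(r.passes_genomewide)}\n"
            )


def _write_windows(windows, value_field: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"chrom\tstart\tend\tn_sites\t{value_field}\n")
        for w in windows:
            val = getattr(w, value_field)
            txt = "NA" if val is None else f"{val:.6g}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites}\t{txt}\n")
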