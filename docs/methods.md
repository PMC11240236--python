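# Methods

## Model and procedure

`sexscan` targets species with genetically determined sex but
cytologically undifferentiated sex chromosomes. Under male heterogamety
(XX/XY) the Y-limited portion of the genome leaves two signatures in a
sexed resequencing cohort mapped to a single (male) reference:

* **Genotypic**: at an X/Y fixed difference, every male is heterozygous
  (one X allele, one Y allele) and every female is homozygous for the X
  allele. With n_m males and n_f females, the probability that an
  autosomal Hardy–Weinberg site mimics this pattern is at most
  2·0.5^(n_m+n_f) (maximized at allele frequency 0.5), i.e. negligible
  for cohorts of tens of individuals — which is why the perfect-linkage
  screen, not the association p-value, is the decisive filter.
* **Coverage**: sequence present only on the Y is hemizygous in males
  (copy number 1 → normalized depth ≈ 0.5) and absent in females (copy
  number 0 → normalized depth ≈ 0, up to mismapping).

The pipeline runs: hard genotype/site filters → Fisher exact sex
association + perfect-linkage screen (+ PCA QC) → windowed Fst and θπ →
depth normalization, 50-bp binning and region calling → gene-interval
classification → a heterogamety verdict (XY/ZW/none) requiring
colocalization of pattern SNPs with depth regions.

## Statistics

**Association.** A mixed-model association step is deliberately not
reimplemented: kinship correction matters for quantitative traits in
structured cohorts, but at the fully sex-linked sites that constitute a
sex-determination signal any valid test saturates, and the
perfect-linkage screen applied on top is stricter than any p-value
threshold. The package therefore tests the 2×2 allele-count table
(rows male/female, columns REF/ALT over called genotypes) with a
two-sided Fisher exact test and exposes genotype PCA (dosage coding,
missing imputed to the site mean, SVD, deterministic sign convention) as
a structure diagnostic. The genome-wide threshold is Bonferroni,
−log₁₀(α/n_tests), with α defaulting to 0.01.

**Fst.** `wc84` (default) computes Weir & Cockerham's variance
components per site from allele frequencies, sample sizes and observed
heterozygosities of the two sex groups, and combines windows as
Σa/Σ(a+b+c) (ratio of sums, the convention of the standard VCF tooling);
small negative values are expected sampling noise. `wright` computes
(H_T − H_S)/H_T with allele-count weighting and is used for closed-form
tests (0 at equal frequencies, 1 at a fixed difference). Sites
monomorphic over both groups, or with a group entirely missing, are
excluded from window sums; windows with no usable site are undefined.

**θπ.** Per SNP, the unbiased estimator 2p(1−p)·2n/(2n−1) over the 2n
called alleles of the group — identical to the mean pairwise difference
among those alleles (verified by exhaustive enumeration in tests) —
summed per window and divided by window width in bp, so invariant
sites count as zero differences.

**Depth scan.** Normalized depth = site depth / sample genome-wide mean
depth (from the manifest, or column means of the depth table when
absent). Bins of 50 bp are indexed by (pos−1)//50; a bin qualifies as
male-specific when the female group mean is ≤ 0.05 and the male group
mean lies in [0.3, 0.7]; qualifying runs are merged across gaps ≤ 150 bp
(3 bins) and calls shorter than 200 bp are dropped. These thresholds
are an explicit operationalization (no published numeric rule exists):
the band is symmetric about the hemizygous expectation 0.5 and wide
enough that Poisson noise at ≥20× group-mean coverage essentially never
ejects a true bin, while the 150-bp merge gap can never bridge the
800-bp gap that separates the closest pair of published regions. Bins
straddling a true boundary dilute the group means, so called boundaries
are accurate to ±1 bin (±50 bp). A mirrored mode swaps the group roles
to call W/X-specific regions.

**Alignment and markers.** X/Y haplotype comparison uses optimal global
affine-gap alignment (match +1, mismatch −1, gap open −4, gap extend −1,
a length-L gap costing open + L·extend; engine: Biopython's
PairwiseAligner, score-checked against an independent exhaustive
recursion for short sequences). Maximal gap runs ≥ min_len become
candidate sex-specific insertions. In-silico PCR scans both template
orientations for primer sites with at most the allowed mismatches and
an exactly matching 3'-terminal base (extension chemistry; N never
matches); product size spans both primer footprints, half-open. Marker
design emits (i) pairs fully inside an insertion (amplify the carrier
only) and (ii) pairs anchored by one insertion primer with the mate in
shared flank (presence/size-shift markers); every candidate is verified
by in-silico PCR on both haplotypes and discarded if the non-carrier
yields any product. Thermodynamic scoring (Tm, dimers) is out of scope.

**Verdict.** `infer_system` returns XY when ≥5 XY-pattern SNPs lie
within 10 Mb of a male-specific depth region on the same chromosome
(ZW mirrored); both thresholds are policy defaults, configurable.

## Synthetic cohort generator

The generator emulates the observable surface of a resequencing
experiment, not the sequencing itself: no reads and no aligner, because
the downstream signals consume only genotype calls and the per-site
depth table. Defaults are the reference study conditions: 31 males and
60 females; three Y-only segments of 400/1,100/1,000 bp at coordinates
3,187,350–3,187,750 / 3,195,150–3,196,250 / 3,197,050–3,198,050 on a
3.3-Mb chromosome; 232 fully sex-linked SNPs; background SNP density
9.4×10⁻⁴/bp (≈551.8k SNPs over a 586.5-Mb genome); per-copy coverage
λ = 20 reads/site (≈40× diploid); lognormal per-sample coverage factors
with sd 0.1 (mean exactly 1); genotype error 0.5% (symmetric state
flip) and missingness 2% — the last two are fixture choices, as no
published error rates exist for the source calls. Depth is
Poisson(copy_number·λ·s_i) per site; copy number is 2 on shared
sequence and 1/0 (males/females) inside male-specific segments. The
manifest's per-sample mean depth is the expected genome-wide value
2λs_i. All randomness derives from a mandatory seed through
fixed-purpose child streams, so identical configs give byte-identical
VCF, depth table and truth JSON.

Coordinate conventions: the reference frame is the male (Y) chromosome;
the X record is the frame minus the Y-only segments (plus any
configured X-only insertions). At sex-linked SNPs the VCF REF is the X
allele — so females are hom_ref, matching an XX individual mapping
cleanly — which means the emitted reference FASTA carries the ALT base
at those positions. X-specific segments affect only the FASTA: their
depth signature is unobservable when mapping against a male reference
(the mirrored region-caller mode covers the ZW/X-specific analysis
path instead).

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: mismapping and repeat-driven coverage
artifacts (female depth in Y-only regions is exactly 0 here, never
merely small), GC and mappability bias, linkage disequilibrium and
recombination structure, relatedness/population structure, multi-allelic
sites and indel calls, and batch effects in coverage. On real cohorts
the female ceiling and the male band exist precisely to absorb the
first of these.

## Numerical and design choices

* Internal intervals are 0-based half-open (length = end − start), which
  reproduces the published region lengths (e.g. 3,187,750 − 3,187,350 =
  400); VCF/GFF3 1-based coordinates are converted at the boundary.
  Multiallelic VCF records are dropped by default (optionally split).
* Filter thresholds are inclusive (≥ keeps); calls below the
  per-genotype DP floor are set missing *before* site-level filters, so
  a site can survive the loss of individual calls.
* Fisher p-values are clamped to (0, 1]; untestable sites (a sex group
  entirely missing) are flagged rather than dropped silently.
* PCA uses a deterministic sign convention (largest-magnitude loading
  positive) so repeated runs are bit-identical; requesting more
  components than the matrix rank truncates with a warning.
* Alignment tie-breaks follow the engine's deterministic traceback;
  only scores, identities and gap-run geometry are consumed downstream,
  none of which depend on tie-break order for the fixtures used.
* The packaged X/Y gene templates are synthetic stand-ins (the true
  genomic sequences are not published): random sequence with the four
  published primer sites planted so that the insertion-internal pair
  yields a 404-bp product and the anchored pair 359 bp on the intact Y
  haplotype, 180 bp on a 179-bp-deletion variant, and nothing on X.
* Problem sizes in tests and the acceptance script (50-kb chromosomes
  for unit tests; 1-Mb and 300-kb depth stretches for recovery runs)
  are chosen so the full suite runs in well under a minute of compute
  per scenario while every rate and threshold stays at study scale.

## Known limitations

* Association is marginal (Fisher exact); no kinship/mixed-model
  correction, genomic control or FDR — by design, see above.
* The depth caller is a thresholding scanner, not a segmentation model
  (no HMM/CBS); very low coverage (λ ≲ 5) will fragment regions.
* In-silico PCR treats primers as exact oligos with a mismatch budget;
  no thermodynamics, so designed markers are candidates for bench
  validation, not guaranteed assays.
* ZW support mirrors the XY logic (pattern screen, mirrored caller);
  a female reference genome is assumed in that case.
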