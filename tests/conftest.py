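import numpy as np
import pytest

from sexscan.seqio import HET, HOM_ALT, HOM_REF, Cohort, Sample, Sex, VariantSite
from sexscan.simcohort import (
    SimConfig,
    make_cohort,
    simulate_genotypes,
    simulate_haplotypes,
)

#: three-segment architecture (400/1,100/1,000 bp, 800-bp gap between the
#: last two) scaled onto a 50-kb chromosome for fast tests
SMALL_SEGMENTS = ((10_000, 10_400), (20_000, 21_100), (21_900, 22_900))


def small_config(**overrides) -> SimConfig:
    base = dict(
        chrom_length=50_000,
        male_specific_segments=SMALL_SEGMENTS,
        n_sexlinked_snps=30,
        autosomal_snp_density=0.01,
        genotype_missing_rate=0.0,
        genotype_error_rate=0.0,
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free 50-kb simulated cohort: (config, truth, cohort, sites)."""
    cfg = small_config()
    _, _, truth = simulate_haplotypes(cfg)
    cohort = make_cohort(cfg)
    sites = simulate_genotypes(truth, cohort, cfg)
    return cfg, truth, cohort, sites


@pytest.fixture
def tiny_cohort():
    """3 males + 3 females with unit mean depth, for hand-built sites."""
    return Cohort(
        [Sample(f"M{i}", Sex.MALE, 30.0) for i in range(3)]
        + [Sample(f"F{i}", Sex.FEMALE, 30.0) for i in range(3)]
    )


def make_site(genotypes, pos=100, chrom="chr1", dp=None):
    return VariantSite(chrom, pos, "A", "G", np.array(genotypes, dtype=np.int8), dp)


def sexlinked_site(n_males, n_females, pos=100):
    """Fully sex-linked site: males het, females hom_ref (cohort order M then F)."""
    return make_site([HET] * n_males + [HOM_REF] * n_females, pos=pos)
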