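import numpy as np
import pytest

from sexlinkage.io_formats import SampleInfo, VariantRecord
from sexlinkage.synthetic_data import SimulationConfig, simulate_observation, simulate_truth


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down cohort: full study design, fewer background SNPs."""
    return SimulationConfig(
        n_background_snps=3000,
        sex_region=("chr8", 21_000_000, 22_200_000, 120),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(truth, observed records) for the scaled-down XY cohort."""
    truth = simulate_truth(small_config)
    records = simulate_observation(
        truth, small_config.mean_coverage, small_config.error_rate, seed=99
    )
    return truth, records


@pytest.fixture
def toy_samples():
    """Four females and four males across two strata."""
    out = []
    for i in range(4):
        out.append(SampleInfo(f"F{i}", "female", "pop1" if i < 2 else "pop2"))
    for i in range(4):
        out.append(SampleInfo(f"M{i}", "male", "pop1" if i < 2 else "pop2"))
    return out


def make_record(chrom="chr1", pos=100, ref="A", alt="T", qual=60.0,
                genotypes=(0, 1), depths=None, allele_depths=None):
    """Build a VariantRecord with consistent default DP/AD."""
    genotypes = np.array(genotypes, dtype=np.int8)
    n = genotypes.size
    if depths is None:
        depths = np.where(genotypes == -1, 0, 4)
    if allele_depths is None:
        allele_depths = np.zeros((n, 2), dtype=np.int32)
        for i, g in enumerate(genotypes):
            d = depths[i]
            if g == 0:
                allele_depths[i] = (d, 0)
            elif g == 1:
                allele_depths[i] = (d - d // 2, d // 2)
            elif g == 2:
                allele_depths[i] = (0, d)
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual,
                         genotypes=genotypes, depths=depths,
                         allele_depths=allele_depths)
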