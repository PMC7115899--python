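"""Population simulator with a known sex-linked region and low-coverage reads.

The generator emulates the statistical structure of a pooled-population
resequencing study of a species with genetic sex determination: a cohort of
48 females and 55 males drawn from four weakly diverged stocks, genotyped at
~2.6x mean per-individual coverage.  Background SNPs are drawn in
Hardy-Weinberg equilibrium within each stratum around a Balding-Nichols
perturbation of an ancestral frequency; sites inside the configured sex
region are fully sex-linked (XY: females hom-ref, males het; ZW mirrored).
Read observation is then simulated per genotype: Poisson depth, equiprobable
allele sampling for heterozygotes, a symmetric per-read error flip, and the
package's genotype-calling rule — so a true heterozygote covered by x reads
is miscalled homozygous with probability 1/2**(x-1), the distortion the
downstream zygosity model quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import genotype_model as gm
from .io_formats import (
    FEMALE,
    MALE,
    SampleInfo,
    VariantRecord,
    write_sample_sheet,
    write_vcf,
)

__all__ = ["SimulationConfig", "TruePopulation", "simulate_truth",
           "simulate_observation", "simulate_read_counts", "emit_dataset"]


@dataclass
class SimulationConfig:
    """Study-design parameters for the simulated cohort.

    Defaults reproduce the emulated study: 48 females / 55 males from four
    equal-probability stocks, a 1.2-Mb fully sex-linked region carrying 500
    SNPs on one of two chromosomes, 50,000 background SNPs, mean per-genotype
    read depth 2.6, per-read error 0.002.
    """

    n_females: int = 48
    n_males: int = 55
    strata: tuple[tuple[str, float], ...] = (
        ("pop1", 0.25), ("pop2", 0.25), ("pop3", 0.25), ("pop4", 0.25),
    )
    chromosomes: tuple[tuple[str, int], ...] = (
        ("chr8", 30_000_000), ("chr21", 20_000_000),
    )
    sex_region: tuple[str, int, int, int] = ("chr8", 21_000_000, 22_200_000, 500)
    n_background_snps: int = 50_000
    bg_freq_prior: tuple[float, float] = (0.5, 0.5)  # Beta(a, b) on ancestral freq
    stratum_divergence: float = 0.02  # Balding-Nichols F
    system: str = "XY"  # "XY" | "ZW" | "none"
    linkage: float = 1.0  # fraction of heterogametic-sex carriers at sex SNPs
    mean_coverage: float = 2.6
    error_rate: float = 0.002
    qual: float = 60.0
    min_allele_reads: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.system not in ("XY", "ZW", "none"):
            raise ValueError(f"system must be XY, ZW or none, got {self.system!r}")
        for p in (self.linkage, self.error_rate, self.stratum_divergence):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.stratum_divergence >= 1.0:
            raise ValueError("stratum_divergence must be < 1")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be > 0")
        chrom, start, end, n_snps = self.sex_region
        lengths = dict(self.chromosomes)
        if chrom not in lengths:
            raise ValueError(f"sex region chromosome {chrom!r} not in chromosomes")
        if not (1 <= start <= end <= lengths[chrom]):
            raise ValueError("sex region outside its chromosome")
        if n_snps > end - start + 1:
            raise ValueError("more sex SNPs requested than region positions")


@dataclass
class TruePopulation:
    """Ground-truth genotypes before any observation noise."""

    samples: list[SampleInfo]
    chroms: np.ndarray  # per-site chromosome name
    positions: np.ndarray  # per-site 1-based position
    true_genotypes: np.ndarray  # int8 (n_sites, n_samples)
    sex_linked: np.ndarray  # bool (n_sites,)

    @property
    def n_sites(self) -> int:
        return int(self.positions.shape[0])


def _assign_strata(labels: list[str], props: np.ndarray, n: int) -> list[str]:
    """Deterministic largest-remainder apportionment of n samples to strata."""
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out: list[str] = []
    for label, c in zip(labels, counts):
        out.extend([label] * c)
    return out


def _make_samples(config: SimulationConfig) -> list[SampleInfo]:
    labels = [s for s, _ in config.strata]
    props = np.array([p for _, p in config.strata], dtype=float)
    props = props / props.sum()
    samples = []
    for sex, n, prefix in ((FEMALE, config.n_females, "F"), (MALE, config.n_males, "M")):
        for i, stratum in enumerate(_assign_strata(labels, props, n), start=1):
            samples.append(SampleInfo(f"{prefix}{i:03d}", sex, stratum))
    return samples


def simulate_truth(config: SimulationConfig) -> TruePopulation:
    """Draw ground-truth genotypes for the configured cohort.

    Background sites: ancestral ref-allele frequency p ~ Beta(a, b); each
    stratum's frequency is a Balding-Nichols resample
    Beta(p(1-F)/F, (1-p)(1-F)/F); genotypes are drawn in HWE within the
    stratum.  Sex-linked sites: the homogametic sex is hom-ref; the
    heterogametic sex is het with probability ``linkage`` else hom-ref.
    """
    rng = np.random.default_rng(config.seed)
    samples = _make_samples(config)
    n_samples = len(samples)
    stratum_of = np.array([s.stratum for s in samples])
    is_male = np.array([s.sex == MALE for s in samples])

    chrom_names = [c for c, _ in config.chromosomes]
    chrom_lens = np.array([l for _, l in config.chromosomes], dtype=float)
    sr_chrom, sr_start, sr_end, n_sex = config.sex_region
    if config.system == "none":
        n_sex_linked = 0
        n_bg = config.n_background_snps + n_sex
    else:
        n_sex_linked = n_sex
        n_bg = config.n_background_snps

    # positions: background uniform over chromosomes (prob ~ length),
    # sex SNPs uniform over the region
    bg_chrom_idx = rng.choice(len(chrom_names), size=n_bg, p=chrom_lens / chrom_lens.sum())
    bg_pos = (rng.random(n_bg) * chrom_lens[bg_chrom_idx]).astype(np.int64) + 1
    sex_pos = rng.choice(np.arange(sr_start, sr_end + 1), size=n_sex_linked, replace=False)

    chroms = np.concatenate([np.array(chrom_names)[bg_chrom_idx],
                             np.full(n_sex_linked, sr_chrom)])
    positions = np.concatenate([bg_pos, sex_pos])
    sex_linked = np.concatenate([np.zeros(n_bg, bool), np.ones(n_sex_linked, bool)])

    genotypes = np.empty((n_bg + n_sex_linked, n_samples), dtype=np.int8)

    # background genotypes, HWE within stratum
    a, b = config.bg_freq_prior
    F = config.stratum_divergence
    p_anc = rng.beta(a, b, size=n_bg)
    for label in {s for s, _ in config.strata}:
        cols = np.flatnonzero(stratum_of == label)
        if cols.size == 0:
            continue
        if F > 0:
            alpha = p_anc * (1 - F) / F
            beta = (1 - p_anc) * (1 - F) / F
            p_k = rng.beta(np.clip(alpha, 1e-9, None), np.clip(beta, 1e-9, None))
        else:
            p_k = p_anc
        # genotype code = alt-allele dosage; alt frequency q = 1 - p_k
        q = 1.0 - p_k
        genotypes[:n_bg, cols] = rng.binomial(
            2, q[:, None], size=(n_bg, cols.size)
        ).astype(np.int8)

    # sex-linked genotypes
    if n_sex_linked:
        hetero_sex = is_male if config.system == "XY" else ~is_male
        block = np.zeros((n_sex_linked, n_samples), dtype=np.int8)
        carriers = rng.random((n_sex_linked, n_samples)) < config.linkage
        block[:, hetero_sex] = np.where(
            carriers[:, hetero_sex], gm.HET, gm.HOM_REF
        ).astype(np.int8)
        genotypes[n_bg:] = block

    # sort by (chrom in declared order, pos)
    chrom_rank = {c: i for i, c in enumerate(chrom_names)}
    order = np.lexsort((positions, np.array([chrom_rank[c] for c in chroms])))
    return TruePopulation(
        samples=samples,
        chroms=chroms[order],
        positions=positions[order],
        true_genotypes=genotypes[order],
        sex_linked=sex_linked[order],
    )


def simulate_read_counts(
    true_genotypes: np.ndarray, depths: np.ndarray, error_rate: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (ref_reads, alt_reads) given true genotypes and read depths.

    Heterozygotes: each read samples an allele with probability 1/2 (a
    symmetric error flip leaves that probability at 1/2).  Homozygotes: all
    reads show the true allele, each flipped with probability ``error_rate``.
    """
    d = np.asarray(depths)
    g = np.asarray(true_genotypes)
    p_ref = np.empty(g.shape, dtype=float)
    p_ref[g == gm.HOM_REF] = 1.0 - error_rate
    p_ref[g == gm.HET] = 0.5
    p_ref[g == gm.HOM_ALT] = error_rate
    p_ref[g == gm.MISSING] = 0.0
    ref = rng.binomial(d, p_ref)
    return ref, d - ref


def simulate_observation(
    truth: TruePopulation,
    mean_coverage: float,
    error_rate: float,
    seed: int,
    qual: float = 60.0,
    min_allele_reads: int = 1,
) -> list[VariantRecord]:
    """Simulate low-coverage genotype observation of a true population.

    Per sample per site: depth ~ Poisson(mean_coverage); reads are drawn per
    :func:`simulate_read_counts`; the genotype is called from the read
    counts; depth 0 yields a missing call.  Returns coordinate-sorted
    biallelic records with GT/DP/AD filled and constant QUAL.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    shape = truth.true_genotypes.shape
    depths = rng.poisson(mean_coverage, size=shape)
    ref, alt = simulate_read_counts(truth.true_genotypes, depths, error_rate, rng)
    called = gm.call_genotypes(ref, alt, min_allele_reads=min_allele_reads)

    # random ref/alt base pair per site (cosmetic; downstream uses codes)
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=shape[0])
    alt_idx = (ref_idx + rng.integers(1, 4, size=shape[0])) % 4
    ref_base, alt_base = bases[ref_idx], bases[alt_idx]

    records = []
    for i in range(shape[0]):
        records.append(
            VariantRecord(
                chrom=str(truth.chroms[i]),
                pos=int(truth.positions[i]),
                ref=str(ref_base[i]),
                alt=str(alt_base[i]),
                qual=qual,
                genotypes=called[i],
                depths=depths[i].astype(np.int32),
                allele_depths=np.stack([ref[i], alt[i]], axis=1).astype(np.int32),
            )
        )
    return records


def emit_dataset(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write VCF, sample sheet and truth table for a simulated cohort.

    The truth table records, per site, the sex-linked flag and every true
    genotype code, so downstream results can be scored against ground truth.
    Outputs are byte-identical across runs with the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_truth(config)
    # derive the observation seed from the config seed (kept below 2**31)
    obs_seed = (config.seed * 2654435761 + 1) % (2**31)
    records = simulate_observation(
        truth, config.mean_coverage, config.error_rate, obs_seed,
        qual=config.qual, min_allele_reads=config.min_allele_reads,
    )
    paths = {
        "vcf": outdir / "genotypes.vcf",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_vcf(records, [s.sample_id for s in truth.samples], paths["vcf"])
    write_sample_sheet(truth.samples, paths["samples"])
    truth_df = pd.DataFrame(
        {"chrom": truth.chroms, "pos": truth.positions,
         "sex_linked": truth.sex_linked.astype(int)}
    )
    gt_df = pd.DataFrame(
        truth.true_genotypes, columns=[s.sample_id for s in truth.samples]
    )
    pd.concat([truth_df, gt_df], axis=1).to_csv(paths["truth"], sep="\t", index=False)
    return paths
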