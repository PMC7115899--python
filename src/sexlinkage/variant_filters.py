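"""Site-level SNP filters and the sex-specific indel screen.

SNP sites are dropped when their quality is below 20, their minor allele
frequency below 0.01, or they fail an exact Hardy-Weinberg test; genotypes
with depth below 2 are masked to missing before the site statistics are
computed (the depth-1 data remain available to the zygosity model, which is
why masking rather than site removal is the default).  Indels are screened
for strict sex specificity: present in every individual with data of one sex
and in none of the other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .genotype_model import HET, HOM_ALT, HOM_REF, MISSING
from .io_formats import FEMALE, MALE, SampleInfo, VariantRecord

__all__ = [
    "FilterThresholds",
    "hwe_exact_test",
    "apply_snp_filters",
    "filter_sex_specific_indels",
    "SexSpecificIndel",
]


@dataclass
class FilterThresholds:
    maf_min: float = 0.01
    qual_min: float = 20.0
    dp_min: int = 2  # per-genotype depth mask
    hwe_alpha: float = 1e-6
    indel_max_missing: float = 0.30

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if self.dp_min < 1:
            raise ValueError("dp_min must be >= 1")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must be in (0, 1)")
        if not 0.0 <= self.indel_max_missing <= 1.0:
            raise ValueError("indel_max_missing must be in [0, 1]")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def _hwe_p_cached(obs_het: int, n_rare: int, n_genotypes: int) -> float:
    """Exact conditional HWE p given rare-allele copies and sample size.

    The conditional distribution of the heterozygote count given the allele
    counts is evaluated with the standard two-way recurrence (numerically
    stable, no factorials); the two-sided p sums every heterozygote count
    whose conditional probability does not exceed the observed one.
    """
    # heterozygote counts share the parity of the rare-allele count
    het_min = n_rare % 2
    # rare homozygotes (n_rare - het)/2 and common homozygotes must be >= 0
    het_max = min(n_rare, 2 * n_genotypes - n_rare)
    n_levels = (het_max - het_min) // 2 + 1
    probs = np.zeros(n_levels, dtype=float)

    # start at the modal heterozygote count and recurse outwards
    mid = int(round(n_rare * (2 * n_genotypes - n_rare) / (2.0 * n_genotypes)))
    if mid % 2 != het_min:
        mid += 1
    mid = min(max(mid, het_min), het_max)
    idx_mid = (mid - het_min) // 2
    probs[idx_mid] = 1.0

    # downward: P(het-2)/P(het) = het(het-1) / (4 * hom_r(het-2)+... )
    het = mid
    for i in range(idx_mid, 0, -1):
        hom_r = (n_rare - het) // 2
        hom_c = n_genotypes - het - hom_r
        probs[i - 1] = probs[i] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
    # upward: P(het+2)/P(het) = 4 hom_r hom_c / ((het+2)(het+1))
    het = mid
    for i in range(idx_mid, n_levels - 1):
        hom_r = (n_rare - het) // 2
        hom_c = n_genotypes - het - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2

    probs /= probs.sum()
    p_obs = probs[(obs_het - het_min) // 2]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Returns the probability, conditional on the observed allele counts, of
    heterozygote counts at most as probable as the observed one.  Monomorphic
    sites return 1.0 (only one configuration exists).
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if n_rare == 0:
        return 1.0
    return _hwe_p_cached(n_het, n_rare, n)


# ---------------------------------------------------------------------------
# SNP site filters
# ---------------------------------------------------------------------------

def _mask_low_depth(record: VariantRecord, dp_min: int) -> VariantRecord:
    """Copy a record with genotypes below the depth threshold set missing.

    Depths recorded as -1 (unknown) are left untouched.
    """
    mask = (record.depths >= 0) & (record.depths < dp_min) & (record.genotypes != MISSING)
    if not mask.any():
        return record
    genotypes = record.genotypes.copy()
    genotypes[mask] = MISSING
    return replace(record, genotypes=genotypes)


def apply_snp_filters(
    records: list[VariantRecord],
    samples: list[SampleInfo],
    thresholds: FilterThresholds | None = None,
    per_stratum_hwe: bool = False,
):
    """Apply the site filters in order QUAL -> call rate -> MAF -> HWE.

    Genotype-level depth masking (DP < dp_min -> missing) is applied before
    any site statistic.  Returns (kept records, removal counts per rule);
    counts sum to ``len(records) - len(kept)``.  With ``per_stratum_hwe``
    the HWE test runs within each stratum and the site is removed if any
    stratum rejects (pooled testing is the default but is confounded by
    population structure and by sex linkage itself).
    """
    thresholds = thresholds or FilterThresholds()
    strata: dict[str, np.ndarray] = {}
    if per_stratum_hwe:
        labels = np.array([s.stratum for s in samples])
        strata = {lab: np.flatnonzero(labels == lab) for lab in dict.fromkeys(labels)}

    kept: list[VariantRecord] = []
    removed = {"qual": 0, "no_calls": 0, "maf": 0, "hwe": 0}
    for rec in records:
        rec = _mask_low_depth(rec, thresholds.dp_min)
        if not (rec.qual >= thresholds.qual_min):  # NaN QUAL also fails
            removed["qual"] += 1
            continue
        g = rec.genotypes
        called = g != MISSING
        n_called = int(called.sum())
        if n_called == 0:
            removed["no_calls"] += 1
            continue
        alt_alleles = int(g[called].sum())
        af = alt_alleles / (2.0 * n_called)
        if min(af, 1.0 - af) < thresholds.maf_min:
            removed["maf"] += 1
            continue
        if per_stratum_hwe:
            ps = []
            for cols in strata.values():
                gs = g[cols]
                counts = [int((gs == c).sum()) for c in (HOM_REF, HET, HOM_ALT)]
                if sum(counts) > 0:
                    ps.append(hwe_exact_test(*counts))
            p_hwe = min(ps) if ps else 1.0
        else:
            counts = [int((g == c).sum()) for c in (HOM_REF, HET, HOM_ALT)]
            p_hwe = hwe_exact_test(*counts)
        if p_hwe < thresholds.hwe_alpha:
            removed["hwe"] += 1
            continue
        kept.append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# Sex-specific indels
# ---------------------------------------------------------------------------

@dataclass
class SexSpecificIndel:
    """An indel carried by every individual-with-data of exactly one sex.

    ``n_hom_alt``/``n_het`` are the carrier-sex genotype counts (the A/H
    columns of the indel report).
    """

    record: VariantRecord
    sex: str  # carrier sex, "female" | "male"
    n_hom_alt: int
    n_het: int

    @property
    def indel_size(self) -> int:
        return abs(len(self.record.alt) - len(self.record.ref))

    @property
    def indel_type(self) -> str:
        return "insertion" if len(self.record.alt) > len(self.record.ref) else "deletion"


def filter_sex_specific_indels(
    records: list[VariantRecord],
    samples: list[SampleInfo],
    max_missing: float = 0.30,
) -> list[SexSpecificIndel]:
    """Screen indel records for strict sex specificity.

    An indel is kept only if (a) at most ``max_missing`` of all genotypes
    are missing, (b) every individual with data of the carrier sex carries
    it (het or hom-alt, no hom-ref), and (c) no individual with data of the
    other sex carries it.  Carrying means het or hom-alt; hom-ref is
    absence.
    """
    is_female = np.array([s.sex == FEMALE for s in samples])
    out: list[SexSpecificIndel] = []
    for rec in records:
        g = rec.genotypes
        if (g == MISSING).mean() > max_missing:
            continue
        label = None
        for sex, cols in ((FEMALE, is_female), (MALE, ~is_female)):
            own = g[cols]
            other = g[~cols]
            own_data = own[own != MISSING]
            other_data = other[other != MISSING]
            if own_data.size == 0:
                continue
            all_carry = np.all((own_data == HET) | (own_data == HOM_ALT))
            none_other = np.all(other_data == HOM_REF) if other_data.size else True
            if all_carry and none_other:
                label = sex
                out.append(
                    SexSpecificIndel(
                        record=rec,
                        sex=sex,
                        n_hom_alt=int((own_data == HOM_ALT).sum()),
                        n_het=int((own_data == HET).sum()),
                    )
                )
                break
        # non-sex-specific indels fall through
    return out
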