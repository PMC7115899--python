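"""Low-coverage zygosity model.

At read depth *x*, a truly homozygous genotype always yields *x* identical
reads, ``P(x | hom) = 1``.  A truly heterozygous genotype yields identical
reads only when every read happens to sample the same allele, which (reads
drawn independently with probability 1/2 per allele) happens with probability

    P(x | het) = 1 / 2**(x - 1)

so heterozygosity is *detected* (both alleles seen at least once) with
probability ``1 - 1/2**(x-1)``.  These closed forms drive everything else in
the package: the expected homozygote excess at low coverage, the posterior
probability that an all-identical-read genotype is truly homozygous, and the
genotype-calling rule used on simulated read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

__all__ = [
    "CoverageProfile",
    "p_identical_given_het",
    "p_identical_given_hom",
    "detection_rate",
    "posterior_hom_given_identical",
    "call_genotype",
    "call_genotypes",
    "expected_hom_proportion_under_depth",
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
]

# Genotype codes used throughout the package (alt-allele dosage; -1 missing).
HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

GENOTYPE_LABELS = {HOM_REF: "hom_ref", HET: "het", HOM_ALT: "hom_alt", MISSING: "missing"}
GENOTYPE_CODES = {v: k for k, v in GENOTYPE_LABELS.items()}


@dataclass
class CoverageProfile:
    """Histogram of genotype observations by read depth.

    ``counts[x]`` is the number of genotype calls backed by ``x`` reads,
    for integer depths x >= 1.
    """

    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for x, n in self.counts.items():
            if x < 1:
                raise ValueError(f"coverage levels must be >= 1, got {x}")
            if n < 0:
                raise ValueError(f"counts must be >= 0, got {n} at coverage {x}")

    @classmethod
    def from_depths(cls, depths: np.ndarray) -> "CoverageProfile":
        depths = np.asarray(depths)
        depths = depths[depths >= 1]
        levels, counts = np.unique(depths, return_counts=True)
        return cls({int(x): int(n) for x, n in zip(levels, counts)})

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def pmf(self) -> dict[int, float]:
        t = self.total
        if t == 0:
            raise ValueError("empty coverage profile")
        return {x: n / t for x, n in self.counts.items() if n > 0}


def _check_x(x) -> np.ndarray:
    arr = np.asarray(x)
    if not np.issubdtype(arr.dtype, np.integer) and not np.all(arr == np.floor(arr)):
        raise ValueError("read count x must be integral")
    if np.any(arr < 1):
        raise ValueError("read count x must be >= 1")
    return arr


def p_identical_given_het(x):
    """Probability that all *x* reads of a true heterozygote show one allele."""
    arr = _check_x(x)
    out = np.exp2(1.0 - arr.astype(float))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def p_identical_given_hom(x):
    """Probability that all *x* reads of a true homozygote are identical (= 1)."""
    arr = _check_x(x)
    out = np.ones_like(arr, dtype=float)
    return 1.0 if np.isscalar(x) or arr.ndim == 0 else out


def detection_rate(x):
    """Probability that *x* reads reveal a true heterozygote, 1 - 1/2**(x-1)."""
    arr = _check_x(x)
    out = 1.0 - np.exp2(1.0 - arr.astype(float))
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def posterior_hom_given_identical(x, prior_hom: float) -> float:
    """Posterior P(hom | x identical reads) for a homozygosity prior.

    Bayes' rule with likelihoods P(x|hom)=1 and P(x|het)=1/2**(x-1):

        prior / (prior + (1 - prior) / 2**(x-1))

    At x=1 a single read is uninformative and the posterior equals the prior.
    """
    _check_x(x)
    if not 0.0 <= prior_hom <= 1.0:
        raise ValueError(f"prior must be in [0, 1], got {prior_hom}")
    lik_het = p_identical_given_het(x)
    denom = prior_hom + (1.0 - prior_hom) * lik_het
    if denom == 0.0:  # prior 0 and lik_het 0 cannot co-occur for finite x
        return 0.0
    return prior_hom / denom


def call_genotype(ref_reads: int, alt_reads: int, min_allele_reads: int = 1) -> int:
    """Call a genotype from per-allele read counts.

    No reads -> MISSING.  Both alleles supported by at least
    ``min_allele_reads`` reads -> HET (any second-allele read reveals
    heterozygosity).  Otherwise the majority allele is called homozygous;
    an exact tie below the het threshold is also called HET.
    """
    if ref_reads < 0 or alt_reads < 0:
        raise ValueError("read counts must be >= 0")
    if ref_reads == 0 and alt_reads == 0:
        return MISSING
    if ref_reads >= min_allele_reads and alt_reads >= min_allele_reads:
        return HET
    if ref_reads == alt_reads:
        return HET
    return HOM_REF if ref_reads > alt_reads else HOM_ALT


def call_genotypes(
    ref_reads: np.ndarray, alt_reads: np.ndarray, min_allele_reads: int = 1
) -> np.ndarray:
    """Vectorised :func:`call_genotype` over arrays of read counts."""
    ref = np.asarray(ref_reads)
    alt = np.asarray(alt_reads)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be >= 0")
    out = np.full(ref.shape, MISSING, dtype=np.int8)
    covered = (ref + alt) > 0
    het = covered & (
        ((ref >= min_allele_reads) & (alt >= min_allele_reads)) | (ref == alt)
    )
    out[het] = HET
    hom_r = covered & ~het & (ref > alt)
    hom_a = covered & ~het & (alt > ref)
    out[hom_r] = HOM_REF
    out[hom_a] = HOM_ALT
    return out


DepthLaw = Union[CoverageProfile, Mapping[int, float], "object"]


def _depth_pmf(depth_law: DepthLaw) -> dict[int, float]:
    """Normalise the accepted depth-law inputs to a finite {x: prob} dict."""
    if isinstance(depth_law, CoverageProfile):
        return depth_law.pmf()
    if isinstance(depth_law, Mapping):
        total = float(sum(depth_law.values()))
        if total <= 0:
            raise ValueError("depth law has no mass")
        return {int(x): v / total for x, v in depth_law.items() if v > 0}
    if hasattr(depth_law, "pmf"):  # scipy.stats frozen discrete distribution
        hi = int(depth_law.ppf(1.0 - 1e-13)) + 2
        xs = np.arange(0, hi + 1)
        pm = depth_law.pmf(xs)
        return {int(x): float(p) for x, p in zip(xs, pm) if p > 0}
    raise TypeError(f"unsupported depth law: {type(depth_law)!r}")


def expected_hom_proportion_under_depth(depth_law: DepthLaw, min_depth: int = 1) -> float:
    """Expected fraction of true heterozygotes called homozygous.

    Computes ``E[1/2**(X-1) | X >= min_depth]`` for read depth X distributed
    according to ``depth_law`` — the model-expected homozygous-looking
    proportion among retained genotypes if every genotype were truly
    heterozygous.  ``depth_law`` may be a :class:`CoverageProfile` (empirical
    histogram), a mapping ``{depth: weight}``, or a frozen scipy discrete
    distribution.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    pmf = _depth_pmf(depth_law)
    mass = sum(p for x, p in pmf.items() if x >= min_depth)
    if mass <= 0:
        raise ValueError(f"depth law has no mass at depth >= {min_depth}")
    num = sum(p * 2.0 ** (1 - x) for x, p in pmf.items() if x >= min_depth)
    return num / mass
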