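"""Stratified sex association, genome-wide threshold and region calling.

Each SNP is tested with the Cochran-Mantel-Haenszel chi-square on per-stratum
2x2 allele-count tables (sex x allele, two alleles per called diploid
genotype), which controls for population stratification.  Significance uses
a Bonferroni-corrected threshold; isolated significant SNPs with no
significant neighbour nearby are discarded as potentially spurious, and the
survivors are merged into candidate sex-determining regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_model import MISSING
from .io_formats import FEMALE, SampleInfo, VariantRecord, genotype_matrix

__all__ = [
    "StratifiedAlleleTable",
    "DegenerateTableError",
    "cmh_test",
    "cmh_scan",
    "bonferroni_threshold",
    "associate",
    "filter_isolated_hits",
    "aggregate_regions",
]

# smallest positive normal double; p-values below it are floored and flagged
P_FLOOR = np.finfo(float).tiny


class DegenerateTableError(ValueError):
    """All strata are degenerate; the CMH statistic is undefined."""


@dataclass
class StratifiedAlleleTable:
    """Per-stratum 2x2 sex-by-allele counts for one SNP.

    Arrays are aligned over strata: ``a`` female ref-allele copies,
    ``b`` female alt, ``c`` male ref, ``d`` male alt.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        self.a, self.b, self.c, self.d = (
            np.atleast_1d(np.asarray(x, dtype=float)) for x in (self.a, self.b, self.c, self.d)
        )
        if np.any(self.a < 0) or np.any(self.b < 0) or np.any(self.c < 0) or np.any(self.d < 0):
            raise ValueError("allele counts must be >= 0")

    @classmethod
    def from_genotypes(
        cls, genotypes: np.ndarray, samples: list[SampleInfo]
    ) -> "StratifiedAlleleTable":
        """Build the table for one site from dosage codes and sample metadata."""
        g = np.asarray(genotypes)
        labels = [s.stratum for s in samples]
        strata = list(dict.fromkeys(labels))
        is_female = np.array([s.sex == FEMALE for s in samples])
        lab_arr = np.array(labels)
        rows = []
        for lab in strata:
            in_k = lab_arr == lab
            row = []
            for sex_mask in (is_female, ~is_female):
                gg = g[in_k & sex_mask]
                gg = gg[gg != MISSING]
                alt = int(gg.sum())
                ref = int(2 * gg.size - alt)
                row.extend([ref, alt])
            rows.append(row)
        arr = np.array(rows, dtype=float)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def _cmh_components(a, b, c, d):
    """Per-stratum (a - E) and V terms; degenerate strata contribute zero."""
    r1 = a + b
    r2 = c + d
    c1 = a + c
    c2 = b + d
    n = r1 + r2
    valid = n > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(valid, r1 * c1 / np.where(valid, n, 1.0), 0.0)
        v = np.where(
            valid,
            r1 * r2 * c1 * c2 / (np.where(valid, n, 1.0) ** 2 * np.where(valid, n - 1.0, 1.0)),
            0.0,
        )
    num = np.where(valid, a - e, 0.0)
    return num, v


def cmh_test(table: StratifiedAlleleTable) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square (1 df, no continuity correction).

        chi2 = [sum_k (a_k - E_k)]**2 / sum_k V_k

    with E_k = r1_k c1_k / n_k and V_k = r1_k r2_k c1_k c2_k / (n_k^2 (n_k - 1)).
    Strata with n_k <= 1 or degenerate margins contribute nothing.  Raises
    :class:`DegenerateTableError` when every stratum is degenerate.
    """
    num, v = _cmh_components(table.a, table.b, table.c, table.d)
    denom = float(v.sum())
    if denom <= 0.0:
        raise DegenerateTableError("no stratum with non-degenerate margins")
    chi2 = float(num.sum()) ** 2 / denom
    p = float(stats.chi2.sf(chi2, df=1))
    return chi2, max(p, P_FLOOR)


def cmh_scan(
    genotypes: np.ndarray,
    samples: list[SampleInfo],
    chroms: np.ndarray,
    positions: np.ndarray,
) -> pd.DataFrame:
    """Vectorised CMH test across sites.

    ``genotypes`` is a (n_sites, n_samples) dosage matrix.  Returns a frame
    with columns chrom, pos, chi2, p, neg_log10_p (chi2/p are NaN where the
    statistic is undefined); the p-value is floored at the smallest positive
    normal double, with a ``p_floored`` flag column.
    """
    g = np.asarray(genotypes)
    labels = np.array([s.stratum for s in samples])
    is_female = np.array([s.sex == FEMALE for s in samples])
    strata = list(dict.fromkeys(labels))

    num_total = np.zeros(g.shape[0])
    v_total = np.zeros(g.shape[0])
    called = (g != MISSING)
    dose = np.where(called, g, 0).astype(np.int64)
    for lab in strata:
        in_k = labels == lab
        groups = {}
        for name, mask in (("f", in_k & is_female), ("m", in_k & ~is_female)):
            alt = dose[:, mask].sum(axis=1)
            n_called = called[:, mask].sum(axis=1)
            groups[name] = (2 * n_called - alt, alt)  # (ref, alt)
        a, b = groups["f"]
        c, d = groups["m"]
        num, v = _cmh_components(a.astype(float), b.astype(float),
                                 c.astype(float), d.astype(float))
        num_total += num
        v_total += v

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(v_total > 0, num_total**2 / np.where(v_total > 0, v_total, 1.0), np.nan)
    p = stats.chi2.sf(chi2, df=1)
    floored = p < P_FLOOR
    p = np.where(floored, P_FLOOR, p)
    with np.errstate(divide="ignore", invalid="ignore"):
        nlp = -np.log10(p)
    return pd.DataFrame(
        {
            "chrom": np.asarray(chroms),
            "pos": np.asarray(positions, dtype=np.int64),
            "chi2": chi2,
            "p": p,
            "neg_log10_p": nlp,
            "p_floored": floored,
        }
    )


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, float]:
    """Bonferroni-corrected genome-wide threshold (p cutoff, -log10 cutoff)."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of tests m must be >= 1")
    p_threshold = alpha / m
    return p_threshold, float(-np.log10(p_threshold))


def associate(
    records: list[VariantRecord],
    samples: list[SampleInfo],
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Run the CMH scan over records and mark genome-wide significance.

    ``n_tests`` defaults to the number of sites tested; pass an override to
    reuse a threshold computed for a larger SNP panel.
    """
    chroms = np.array([r.chrom for r in records])
    positions = np.array([r.pos for r in records], dtype=np.int64)
    df = cmh_scan(genotype_matrix(records), samples, chroms, positions)
    m = n_tests if n_tests is not None else max(len(records), 1)
    p_thr, _ = bonferroni_threshold(alpha, m)
    df["significant"] = (df["p"] < p_thr) & df["p"].notna()
    return df


def filter_isolated_hits(
    results: pd.DataFrame, window_bp: int = 100_000, min_neighbors: int = 1
) -> pd.DataFrame:
    """Drop significant SNPs with too few significant neighbours nearby.

    A significant SNP stays significant only if at least ``min_neighbors``
    other significant SNPs lie within ``window_bp`` on the same chromosome.
    Non-significant rows pass through unchanged.
    """
    out = results.copy()
    for chrom, idx in out.groupby("chrom", sort=False).groups.items():
        sub = out.loc[idx]
        sig_pos = np.sort(sub.loc[sub["significant"], "pos"].to_numpy())
        if sig_pos.size == 0:
            continue
        lo = np.searchsorted(sig_pos, sig_pos - window_bp, side="left")
        hi = np.searchsorted(sig_pos, sig_pos + window_bp, side="right")
        n_neighbors = hi - lo - 1  # exclude the SNP itself
        lonely = set(sig_pos[n_neighbors < min_neighbors])
        if lonely:
            mask = sub["significant"] & sub["pos"].isin(lonely)
            out.loc[sub.index[mask], "significant"] = False
    return out


def aggregate_regions(results: pd.DataFrame, max_gap_bp: int = 1_000_000) -> pd.DataFrame:
    """Merge consecutive significant SNPs into regions.

    SNPs on one chromosome whose neighbouring significant positions are at
    most ``max_gap_bp`` apart join one region; bounds are the member min/max
    positions.  Returns a frame with chrom, start, end, n_snps, sorted and
    disjoint.
    """
    rows = []
    sig = results.loc[results["significant"].astype(bool)]
    for chrom, sub in sig.groupby("chrom", sort=False):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [pos.size - 1]])
        for s, e in zip(starts, ends):
            rows.append(
                {"chrom": chrom, "start": int(pos[s]), "end": int(pos[e]),
                 "n_snps": int(e - s + 1)}
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
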