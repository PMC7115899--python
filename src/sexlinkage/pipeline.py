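"""End-to-end orchestration: filter -> associate -> regionize -> zygosity -> annotate.

Given a genotype VCF, a sample sheet (sex + population stratum per sample)
and optionally gene models and a genome, the pipeline reproduces the whole
inference chain and writes a deterministic report bundle: the filtered VCF,
a Manhattan-ready association table, candidate sex regions, genotype tallies
by sex, coverage-stratified homozygosity tables for both sexes, variant
consequences, sex-specific indels and a heterogamety verdict JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import association as assoc
from . import variant_filters as vf
from . import zygosity_analysis as zyg
from .io_formats import (
    FEMALE,
    MALE,
    read_gff,
    read_sample_sheet,
    read_vcf,
    write_vcf,
)

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    samples: str = ""
    outdir: str = "results"
    gff: str | None = None
    fasta: str | None = None
    # filters
    maf_min: float = 0.01
    qual_min: float = 20.0
    dp_min: int = 2
    hwe_alpha: float = 1e-6
    indel_max_missing: float = 0.30
    # association
    alpha: float = 0.05
    n_tests: int | None = None  # override Bonferroni m (default: SNPs tested)
    window_bp: int = 100_000
    min_neighbors: int = 1
    max_gap_bp: int = 1_000_000
    # zygosity
    x_max: int = 21
    min_stratum_n: int = 5
    hom_floor: float = 0.95
    tolerance_se: float = 3.0
    tolerance_abs: float = 0.02
    min_snps: int = 10
    # annotation
    promoter_up: int = 2000
    promoter_down: int = 200
    seed: int = 0

    def thresholds(self) -> vf.FilterThresholds:
        return vf.FilterThresholds(
            maf_min=self.maf_min, qual_min=self.qual_min, dp_min=self.dp_min,
            hwe_alpha=self.hwe_alpha, indel_max_missing=self.indel_max_missing,
        )


_FLAT_KEYS = {f.name for f in PipelineConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]
_SECTIONS = {
    "paths": {"vcf", "samples", "outdir", "gff", "fasta"},
    "filters": {"maf_min", "qual_min", "dp_min", "hwe_alpha", "indel_max_missing"},
    "association": {"alpha", "n_tests", "window_bp", "min_neighbors", "max_gap_bp"},
    "zygosity": {"x_max", "min_stratum_n", "hom_floor", "tolerance_se",
                 "tolerance_abs", "min_snps"},
    "annotation": {"promoter_up", "promoter_down"},
}


def validate_config(raw: dict | None) -> tuple[PipelineConfig, list[str]]:
    """Normalise a parsed YAML mapping into a PipelineConfig.

    Accepts either flat keys or the sectioned layout (paths/filters/
    association/zygosity/annotation); fills documented defaults, checks
    ranges, and returns warnings for unknown keys.
    """
    raw = raw or {}
    flat: dict = {}
    warnings: list[str] = []
    for key, value in raw.items():
        if key in _SECTIONS:
            for k, v in (value or {}).items():
                if k in _SECTIONS[key]:
                    flat[k] = v
                else:
                    warnings.append(f"unknown key {key}.{k} ignored")
        elif key in _FLAT_KEYS:
            flat[key] = value
        else:
            warnings.append(f"unknown key {key} ignored")
    config = PipelineConfig(**flat)
    if not 0.0 < config.alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {config.alpha}")
    if config.dp_min < 1:
        raise ValueError(f"dp_min must be >= 1, got {config.dp_min}")
    config.thresholds()  # range-checks the filter block
    if config.n_tests is not None and config.n_tests < 1:
        raise ValueError("n_tests override must be >= 1")
    if config.x_max < 1:
        raise ValueError("x_max must be >= 1")
    for w in warnings:
        logger.warning(w)
    return config, warnings


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.floating):
        return float(obj)
    return obj


def _strata_frame(strata: list[zyg.CoverageStratum]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"x": s.x, "n": s.n, "n_hom": s.n_hom, "prop_hom": s.prop_hom,
             "expected": s.expected, "ci_low": s.ci_low, "ci_high": s.ci_high,
             "p_exact": s.p_exact}
            for s in strata
        ]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``.

    Deterministic given inputs and config; every threshold used is recorded
    in ``run_config.json``.  Returns the in-memory report (frames, counts,
    verdict, evidence).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    current = stage("read_inputs")
    try:
        records, sample_ids = read_vcf(config.vcf)
        samples = read_sample_sheet(config.samples)
        by_id = {s.sample_id: s for s in samples}
        if list(by_id) != sample_ids:
            samples = [by_id[sid] for sid in sample_ids]  # align to VCF column order
        snps = [r for r in records if r.is_snp]
        indels = [r for r in records if r.is_indel]

        current = stage("filter_snps")
        kept, removed = vf.apply_snp_filters(snps, samples, config.thresholds())
        logger.info("SNP filters: %d -> %d kept, removals %s", len(snps), len(kept), removed)
        write_vcf(kept, sample_ids, outdir / "filtered.vcf")

        current = stage("association")
        results = assoc.associate(kept, samples, alpha=config.alpha, n_tests=config.n_tests)
        m = config.n_tests if config.n_tests is not None else max(len(kept), 1)
        p_thr, nlp_thr = assoc.bonferroni_threshold(config.alpha, m)
        logger.info("Bonferroni: m=%d, p<%.3e, -log10(p)>%.2f", m, p_thr, nlp_thr)
        n_sig_raw = int(results["significant"].sum())
        results = assoc.filter_isolated_hits(
            results, window_bp=config.window_bp, min_neighbors=config.min_neighbors
        )
        n_sig = int(results["significant"].sum())
        logger.info("significant SNPs: %d raw, %d after isolated-hit removal", n_sig_raw, n_sig)
        results.to_csv(outdir / "association.tsv", sep="\t", index=False)
        regions = assoc.aggregate_regions(results, max_gap_bp=config.max_gap_bp)
        regions.to_csv(outdir / "regions.tsv", sep="\t", index=False)

        current = stage("zygosity")
        # zygosity uses the unmasked genotypes (depth-1 calls included)
        sig_keys = set(
            zip(results.loc[results["significant"], "chrom"],
                results.loc[results["significant"], "pos"])
        )
        sex_idx = [i for i, r in enumerate(snps) if (r.chrom, r.pos) in sig_keys]
        report: dict = {
            "n_snps_input": len(snps),
            "n_snps_kept": len(kept),
            "removed": removed,
            "bonferroni": {"m": m, "p_threshold": p_thr, "neg_log10_threshold": nlp_thr},
            "n_significant_raw": n_sig_raw,
            "n_significant": n_sig,
            "association": results,
            "regions": regions,
        }
        if sex_idx:
            agg, per_snp = zyg.count_genotypes_by_sex(snps, samples, sex_idx)
            per_snp.to_csv(outdir / "genotype_counts_per_snp.tsv", sep="\t", index=False)
            counts_df = pd.DataFrame(
                [
                    {"sex": sex, "hom_ref": c.hom_ref, "hom_alt": c.hom_alt,
                     "het": c.het, "available": c.available, "missing": c.missing,
                     "prop_hom": c.prop_hom, "prop_het": c.prop_het}
                    for sex, c in agg.items()
                ]
            )
            counts_df.to_csv(outdir / "genotype_counts.tsv", sep="\t", index=False)
            strata = {}
            for sex, expectation in ((FEMALE, "hom"), (MALE, "het")):
                strata[sex] = zyg.coverage_stratified_homozygosity(
                    snps, samples, sex, x_max=config.x_max,
                    expectation=expectation, min_n=config.min_stratum_n,
                    site_subset=sex_idx,
                )
                _strata_frame(strata[sex]).to_csv(
                    outdir / f"coverage_strata_{sex}.tsv", sep="\t", index=False
                )
            profiles = {
                sex: zyg._coverage_profile(snps, samples, sex, sex_idx)
                for sex in (FEMALE, MALE)
            }
            verdict, evidence = zyg.classify_heterogamety(
                agg[FEMALE], agg[MALE], profiles,
                hom_floor=config.hom_floor, tolerance_se=config.tolerance_se,
                tolerance_abs=config.tolerance_abs, min_snps=config.min_snps,
                n_snps=len(sex_idx),
            )
            evidence["male_trend"] = zyg.male_trend_check(strata[MALE])
            evidence["female_summary"] = zyg.summarize_proportions(strata[FEMALE]) \
                if strata[FEMALE] else None
            report.update(
                {"genotype_counts": agg, "coverage_strata": strata,
                 "verdict": verdict, "evidence": evidence}
            )
        else:
            verdict, evidence = "undetermined", {
                "warning": "no significant sex-associated SNPs", "verdict": "undetermined",
            }
            report.update({"verdict": verdict, "evidence": evidence})
        with open(outdir / "verdict.json", "w") as fh:
            json.dump(_jsonable({"verdict": verdict, "evidence": evidence}), fh, indent=2)

        current = stage("indels")
        sex_indels = vf.filter_sex_specific_indels(
            indels, samples, max_missing=config.indel_max_missing
        )
        indel_df = pd.DataFrame(
            [
                {"chrom": si.record.chrom, "pos": si.record.pos,
                 "sex_specific": "M" if si.sex == MALE else "F",
                 "type": si.indel_type, "size": si.indel_size,
                 "n_hom_alt": si.n_hom_alt, "n_het": si.n_het}
                for si in sex_indels
            ],
            columns=["chrom", "pos", "sex_specific", "type", "size", "n_hom_alt", "n_het"],
        )
        indel_df.to_csv(outdir / "sex_specific_indels.tsv", sep="\t", index=False)
        report["sex_specific_indels"] = indel_df

        if config.gff:
            current = stage("annotation")
            genes = read_gff(config.gff)
            genome = None
            if config.fasta:
                import pyfaidx

                genome = pyfaidx.Fasta(config.fasta)
            sig_records = [snps[i] for i in sex_idx]
            consequences = ann.annotate_variants(
                sig_records, genes, genome,
                promoter_up=config.promoter_up, promoter_down=config.promoter_down,
            )
            pd.DataFrame(
                [
                    {"chrom": c.chrom, "pos": c.pos, "category": c.category,
                     "gene_id": c.gene_id or "", "codon_change": c.codon_change or "",
                     "aa_change": "{}{}{}".format(*c.aa_change) if c.aa_change else "",
                     "aa_class_change": " to ".join(c.aa_class_change)
                     if c.aa_class_change else "",
                     "conservative": "" if c.conservative is None else str(c.conservative)}
                    for c in consequences
                ]
            ).to_csv(outdir / "consequences.tsv", sep="\t", index=False)
            summary = ann.consequence_summary(consequences)
            pd.DataFrame(summary.items(), columns=["category", "n"]).to_csv(
                outdir / "consequence_summary.tsv", sep="\t", index=False
            )
            report["consequences"] = consequences
            report["consequence_summary"] = summary

        with open(outdir / "run_config.json", "w") as fh:
            json.dump(_jsonable(asdict(config)), fh, indent=2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    return report


def load_config(path) -> tuple[PipelineConfig, list[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_config(raw)
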